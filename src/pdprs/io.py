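"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: block files are BED-like, 0-based half-open;
summary statistics carry 1-based positions. Conversion happens at read
time, so everything downstream works with half-open block intervals and
1-based SNP positions.

Allele harmonization: summary-statistic effect sizes are re-oriented so
that ``beta`` always refers to the manifest's effect allele. Records whose
allele pair cannot be reconciled with the manifest (including, by default,
strand-ambiguous A/T and C/G SNPs) are dropped and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

OTHERS = "OTHERS"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default header aliases for summary-statistic columns
SUMSTATS_ALIASES: dict[str, tuple[str, ...]] = {
    "snp": ("SNP", "ID", "RSID", "MARKERNAME", "VARIANT_ID"),
    "chrom": ("CHR", "CHROM", "CHROMOSOME"),
    "pos": ("BP", "POS", "POSITION", "BASE_PAIR_LOCATION"),
    "a1": ("A1", "EFFECT_ALLELE", "ALT", "EA"),
    "a2": ("A2", "OTHER_ALLELE", "REF", "OA", "NEA"),
    "beta": ("BETA", "B", "EFFECT", "EFFECT_SIZE"),
    "se": ("SE", "STDERR", "STANDARD_ERROR"),
    "n": ("N", "NEFF", "SAMPLE_SIZE"),
    "p": ("P", "PVAL", "PVALUE", "P_VALUE"),
}


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class ValidationError(ValueError):
    """Contents violate an invariant (overlap, coverage, dimensions...)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """Per-SNP marginal effect estimates for one trait.

    ``table`` has columns snp, chrom, pos, a1, a2, beta, se, n, p with
    beta on the standardized-genotype scale and a1 the effect allele.
    """

    trait_id: str
    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        t = self.table
        if t["snp"].duplicated().any():
            dup = t.loc[t["snp"].duplicated(), "snp"].iloc[0]
            raise ValidationError(f"duplicate SNP id within trait {self.trait_id!r}: {dup}")
        if (t["se"] <= 0).any():
            raise ValidationError("standard errors must be positive")
        if ((t["p"] < 0) | (t["p"] > 1)).any():
            raise ValidationError("p-values must lie in [0, 1]")
        if (t["a1"] == t["a2"]).any():
            raise ValidationError("effect and other allele must differ")


@dataclass
class LdBlock:
    """One nearly LD-independent region, 0-based half-open."""

    block_id: int
    chrom: str
    start: int
    end: int
    snp_ids: list[str] = field(default_factory=list)

    def contains(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass
class GenotypeMatrix:
    """Dosage matrix with its SNP manifest.

    ``dosages`` is individuals x SNPs, values in [0, 2] (NaN = missing,
    mean-imputed at scoring time). ``a1`` is the counted (effect) allele
    per SNP.
    """

    iids: list[str]
    snps: list[str]
    dosages: np.ndarray
    a1: list[str] | None = None
    a2: list[str] | None = None

    def __post_init__(self) -> None:
        d = self.dosages
        if d.shape != (len(self.iids), len(self.snps)):
            raise ValidationError(
                f"dosage matrix shape {d.shape} does not match "
                f"{len(self.iids)} individuals x {len(self.snps)} SNPs"
            )
        if d.size:
            if np.issubdtype(d.dtype, np.integer):
                lo, hi = d.min(), d.max()
            else:
                lo, hi = np.nanmin(d), np.nanmax(d)
            if lo < 0 or hi > 2:
                raise ValidationError("dosages must lie in [0, 2]")


@dataclass
class ClusterConfig:
    """Ordered pleiotropy-cluster labels and the trait -> cluster map.

    The reserved label ``OTHERS`` names the non-specific cluster and may
    never be assigned to a trait.
    """

    clusters: list[str]
    trait_to_cluster: dict[str, str]

    def __post_init__(self) -> None:
        if OTHERS in self.trait_to_cluster.values():
            bad = [t for t, c in self.trait_to_cluster.items() if c == OTHERS]
            raise ValidationError(f"{OTHERS} is reserved for the non-specific cluster; "
                                  f"assigned to trait(s) {bad}")
        for trait, cl in self.trait_to_cluster.items():
            if cl not in self.clusters:
                raise ValidationError(f"trait {trait!r} maps to unknown cluster {cl!r}")
        if OTHERS not in self.clusters:
            self.clusters = [*self.clusters, OTHERS]

    def cluster_of(self, trait: str) -> str:
        try:
            return self.trait_to_cluster[trait]
        except KeyError:
            raise KeyError(f"trait {trait!r} missing from cluster configuration") from None


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_alleles(table: pd.DataFrame, manifest: pd.DataFrame,
                      ambiguous: str = "drop") -> tuple[pd.DataFrame, int]:
    """Re-orient ``beta`` to the manifest's effect allele.

    ``manifest`` needs columns snp, a1, a2. Strand flips are resolved via
    base complement. Returns the harmonized table (manifest orientation,
    rows restricted to resolvable manifest SNPs) and the count of dropped
    records. ``ambiguous`` in {"drop", "keep"} controls A/T and C/G SNPs;
    when kept they are matched by letter without strand resolution.

    Idempotent: a table already in manifest orientation passes through
    unchanged.
    """
    if ambiguous not in ("drop", "keep"):
        raise ValueError(f"unknown ambiguous-SNP policy {ambiguous!r}")
    man = manifest.set_index("snp")[["a1", "a2"]]
    rows = []
    n_dropped = 0
    for rec in table.itertuples(index=False):
        if rec.snp not in man.index:
            n_dropped += 1
            continue
        ma1, ma2 = man.loc[rec.snp]
        a1, a2 = str(rec.a1).upper(), str(rec.a2).upper()
        ambig = _is_ambiguous(a1, a2)
        if ambig and ambiguous == "drop":
            n_dropped += 1
            continue
        flip = None
        if (a1, a2) == (ma1, ma2):
            flip = False
        elif (a1, a2) == (ma2, ma1):
            flip = True
        elif not ambig:
            ca1 = _COMPLEMENT.get(a1)
            ca2 = _COMPLEMENT.get(a2)
            if (ca1, ca2) == (ma1, ma2):
                flip = False
            elif (ca1, ca2) == (ma2, ma1):
                flip = True
        if flip is None:
            n_dropped += 1
            continue
        d = rec._asdict()
        d["a1"], d["a2"] = ma1, ma2
        if flip:
            d["beta"] = -d["beta"]
        rows.append(d)
    out = pd.DataFrame(rows, columns=list(table.columns))
    return out.reset_index(drop=True), n_dropped


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _resolve_columns(columns: list[str], aliases: dict[str, tuple[str, ...]]) -> dict[str, str]:
    upper = {c.upper(): c for c in columns}
    mapping = {}
    for canon, names in aliases.items():
        for name in names:
            if name in upper:
                mapping[upper[name]] = canon
                break
        else:
            raise FormatError(f"required column {canon!r} (one of {names}) not found "
                              f"in header {columns}")
    return mapping


def read_sumstats(path, trait_id: str | None = None,
                  harmonize_to: pd.DataFrame | None = None,
                  aliases: dict[str, tuple[str, ...]] | None = None,
                  ambiguous: str = "drop") -> SummaryStats:
    """Read a GWAS summary-statistics TSV.

    Required columns (configurable aliases): SNP, CHR, BP, A1, A2, BETA,
    SE, N, P. If ``harmonize_to`` (a SNP manifest with snp/a1/a2 columns)
    is given, effects are flipped to the manifest's effect allele and
    unresolvable records dropped with a count kept on the result.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    mapping = _resolve_columns(list(raw.columns), aliases or SUMSTATS_ALIASES)
    tab = raw.rename(columns=mapping)[list(SUMSTATS_ALIASES)]
    tab["chrom"] = tab["chrom"].astype(str)
    for col in ("a1", "a2"):
        tab[col] = tab[col].astype(str).str.upper()
    n_dropped = 0
    if harmonize_to is not None:
        tab, n_dropped = harmonize_alleles(tab, harmonize_to, ambiguous=ambiguous)
    tid = trait_id if trait_id is not None else str(path)
    return SummaryStats(trait_id=tid, table=tab, n_dropped=n_dropped)


def read_blocks(path, manifest: pd.DataFrame | None = None,
                strict: bool = True) -> list[LdBlock]:
    """Read LD-block definitions (BED3 + block_id, 0-based half-open).

    Blocks are returned sorted by (chrom, start) and validated for
    within-chromosome non-overlap. If a SNP ``manifest`` (columns snp,
    chrom, pos with 1-based pos) is supplied, block SNP membership is
    filled in; with ``strict`` any manifest SNP outside every block is an
    error (the partition must be exhaustive).
    """
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "block_id"],
                      dtype={"chrom": str})
    if bed.isna().any().any():
        raise FormatError(f"{path}: expected 4 columns chrom/start/end/block_id")
    bed = bed.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for chrom, grp in bed.groupby("chrom"):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValidationError(f"overlapping blocks on chromosome {chrom}")
        if (starts >= ends).any():
            raise ValidationError(f"empty or inverted block interval on chromosome {chrom}")
    blocks = [LdBlock(int(r.block_id), str(r.chrom), int(r.start), int(r.end))
              for r in bed.itertuples(index=False)]
    if manifest is not None:
        assign_snps_to_blocks(blocks, manifest, strict=strict)
    return blocks


def assign_snps_to_blocks(blocks: list[LdBlock], manifest: pd.DataFrame,
                          strict: bool = True) -> list[str]:
    """Fill block SNP membership by position; returns unassigned SNP ids.

    Positions are 1-based, intervals 0-based half-open, so a SNP at
    1-based position p belongs to a block iff start <= p-1 < end.
    """
    unassigned = []
    for rec in manifest.itertuples(index=False):
        hit = None
        for b in blocks:
            if str(rec.chrom) == b.chrom and b.contains(int(rec.pos)):
                hit = b
                break
        if hit is None:
            unassigned.append(rec.snp)
        else:
            hit.snp_ids.append(rec.snp)
    if unassigned and strict:
        raise ValidationError(
            f"{len(unassigned)} manifest SNP(s) fall outside all blocks: "
            f"{unassigned[:10]}")
    return unassigned


def read_weights(path) -> pd.DataFrame:
    """Read a PRS weight file: TSV with columns SNP, A1, WEIGHT."""
    w = pd.read_csv(path, sep="\t")
    cols = {c.upper(): c for c in w.columns}
    try:
        w = w.rename(columns={cols["SNP"]: "snp", cols["A1"]: "a1", cols["WEIGHT"]: "weight"})
    except KeyError as exc:
        raise FormatError(f"{path}: weight file needs SNP, A1, WEIGHT columns") from exc
    w["a1"] = w["a1"].astype(str).str.upper()
    return w[["snp", "a1", "weight"]]


# --- PLINK bed/bim/fam ------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit genotype -> dosage of the bim A1 allele; 0b01 encodes missing
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix) -> GenotypeMatrix:
    """Decode a SNP-major PLINK .bed/.bim/.fam triple into dosages of A1."""
    prefix = str(prefix)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    n, p = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not a SNP-major PLINK bed)")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    bytes_per_snp = math.ceil(n / 4)
    if body.size != bytes_per_snp * p:
        raise FormatError(f"{prefix}.bed: expected {bytes_per_snp * p} data bytes, "
                          f"found {body.size}")
    body = body.reshape(p, bytes_per_snp)
    # unpack the four 2-bit fields of each byte (sample order: LSB first)
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeMatrix(iids=list(fam["iid"]), snps=list(bim["snp"]),
                          dosages=dosages, a1=list(bim["a1"]), a2=list(bim["a2"]))


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes from a PLINK prefix or a TSV dosage matrix.

    The TSV layout is one row per individual: an IID column followed by
    one column per SNP holding dosages in [0, 2].
    """
    path = str(path)
    if path.endswith(".bed"):
        return read_plink(path[:-4])
    import os
    if os.path.exists(path + ".bed"):
        return read_plink(path)
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    if "IID" not in df.columns:
        raise FormatError(f"{path}: dosage TSV needs an IID column")
    snps = [c for c in df.columns if c != "IID"]
    return GenotypeMatrix(iids=list(df["IID"]), snps=snps,
                          dosages=df[snps].to_numpy(dtype=float))


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype/covariate TSV keyed by IID.

    Follow-up time (column ``time``, if present) must be non-negative and
    the event indicator (``event``) binary.
    """
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    if "IID" not in df.columns:
        raise FormatError(f"{path}: phenotype table needs an IID column")
    if "time" in df.columns and (df["time"] < 0).any():
        raise ValidationError("negative follow-up time")
    if "event" in df.columns and not df["event"].isin((0, 1)).all():
        raise ValidationError("event indicator must be 0/1")
    return df.set_index("IID")


def read_cluster_config(path) -> ClusterConfig:
    """Read a trait -> cluster map from YAML or two-column text.

    YAML layout: ``clusters: [..]`` (ordered) and ``traits: {trait: cluster}``.
    Plain-text layout: one ``trait<TAB>cluster`` pair per line; cluster
    order follows first appearance.
    """
    text = open(path).read()
    if ":" in text.splitlines()[0]:
        doc = yaml.safe_load(text)
        return ClusterConfig(clusters=list(doc["clusters"]),
                             trait_to_cluster=dict(doc["traits"]))
    mapping: dict[str, str] = {}
    order: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        trait, cluster = line.split("\t")
        mapping[trait] = cluster
        if cluster not in order:
            order.append(cluster)
    return ClusterConfig(clusters=order, trait_to_cluster=mapping)


# ---------------------------------------------------------------------------
# score table round trip
# ---------------------------------------------------------------------------


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a score table (index IID, columns OVERALL + clusters) as TSV."""
    scores.to_csv(path, sep="\t", index_label="IID", float_format="%.12g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"IID": str}).set_index("IID")
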