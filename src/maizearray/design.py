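"""Final array content selection: the voting system, duplicate-probe
resolution, gene annotation, and density statistics.

Variants that are PolyHighResolution both with and without inbred
correction are forwarded unconditionally; stable OTV variants passing
custom cluster-metric thresholds are forwarded too.  The remainder is
ranked by 35 x class-transition weight + 90 x sequence concordance +
10 x bin-representation score and the top variants fill the array to its
target size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._rng import substream
from .containers import AA, AB, BB, HET, HOM_ALT, HOM_REF, MISSING
from .errors import ValidationError

__all__ = [
    "forward_phr_stable",
    "OtvThresholds",
    "select_otv_stable",
    "sequence_concordance",
    "bin_representation_score",
    "rank_variant",
    "resolve_duplicate_probes",
    "assemble_final",
    "annotate_variants",
    "density_stats",
    "ArrayDesign",
]

_PHR = "PolyHighResolution"


def forward_phr_stable(categories: pd.DataFrame) -> list:
    """Ids classified PolyHighResolution both with and without inbred
    correction; ``categories`` needs columns variant_id, category_nocorr,
    category_corr."""
    for col in ("category_nocorr", "category_corr"):
        if col not in categories.columns:
            raise ValidationError(f"categories table lacks column {col!r}")
    mask = (categories["category_nocorr"] == _PHR) & (categories["category_corr"] == _PHR)
    return categories.loc[mask, "variant_id"].tolist()


@dataclass
class OtvThresholds:
    """Custom cluster-metric cuts for forwarding stable OTV variants."""

    max_missing_fraction: float = 0.10
    fld_min: float = 3.5
    hetso_min: float = -3.5
    homro_min: float = 1.0
    homfld_min: float = 5.0


def select_otv_stable(
    categories: pd.DataFrame,
    metrics: pd.DataFrame,
    thresholds: OtvThresholds | None = None,
) -> list:
    """Ids classified OTV in both analyses that are polymorphic, have at
    most 10% missing calls, and pass the metric cuts.

    ``metrics`` (with-correction analysis) needs columns variant_id,
    final_call_rate (percent), fld, het_so, hom_ro, hom_fld,
    n_geno_clusters.  When FLD/HetSO are undefined (two-cluster case) the
    homFLD cut applies instead.
    """
    t = thresholds or OtvThresholds()
    stable = set(
        categories.loc[
            (categories["category_nocorr"] == "OTV")
            & (categories["category_corr"] == "OTV"),
            "variant_id",
        ]
    )
    out = []
    m = metrics.set_index("variant_id")
    for vid in categories["variant_id"]:
        if vid not in stable or vid not in m.index:
            continue
        row = m.loc[vid]
        if row["n_geno_clusters"] <= 1:  # monomorphic target variant
            continue
        if row["final_call_rate"] < 100.0 * (1.0 - t.max_missing_fraction):
            continue
        if pd.isna(row["hom_ro"]) or row["hom_ro"] <= t.homro_min:
            continue
        if pd.isna(row["fld"]) or pd.isna(row["het_so"]):
            if pd.isna(row["hom_fld"]) or row["hom_fld"] <= t.homfld_min:
                continue
        elif row["fld"] <= t.fld_min or row["het_so"] <= t.hetso_min:
            continue
        out.append(vid)
    return out


_ARRAY_TO_SEQ = {AA: HOM_REF, AB: HET, BB: HOM_ALT}


def sequence_concordance(
    array_calls: np.ndarray,
    seq_calls: np.ndarray,
    array_samples: list,
    seq_samples: list,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant fraction of matching calls across the shared discovery
    samples (both matrices samples x variants, array- and sequencing-space
    codes respectively).

    Only pairs where both calls are non-missing (and the array call is not
    OO) are compared.  Variants with no comparable pair get concordance 0
    with a flag.  Returns (concordance, flagged).
    """
    shared = [s for s in array_samples if s in seq_samples]
    if not shared:
        raise ValidationError("no overlapping samples between call sets")
    a_idx = [array_samples.index(s) for s in shared]
    s_idx = [seq_samples.index(s) for s in shared]
    arr = array_calls[a_idx]
    seq = seq_calls[s_idx]
    arr_as_seq = np.full_like(arr, MISSING)
    for a_code, s_code in _ARRAY_TO_SEQ.items():
        arr_as_seq[arr == a_code] = s_code
    comparable = (arr_as_seq != MISSING) & (seq != MISSING)
    n_comp = comparable.sum(axis=0)
    n_match = (comparable & (arr_as_seq == seq)).sum(axis=0)
    flagged = n_comp == 0
    with np.errstate(invalid="ignore"):
        c = np.where(flagged, 0.0, n_match / np.maximum(n_comp, 1))
    return c, flagged


def bin_representation_score(
    bin_counts: np.ndarray, index: int, window: int = 5
) -> float:
    """Representation score of a bin against its neighborhood.

    With m the mean count of up to ``window`` bins on each side (truncated
    at chromosome ends) and n the bin's own count, s = (m - n) / (m + n)
    when m + n > 0, else 0; positive for under-represented bins.
    """
    counts = np.asarray(bin_counts, float)
    if (counts < 0).any():
        raise ValidationError("bin counts must be non-negative")
    lo = max(0, index - window)
    hi = min(len(counts), index + window + 1)
    neigh = np.concatenate([counts[lo:index], counts[index + 1:hi]])
    if neigh.size == 0:
        return 0.0
    m = float(neigh.mean())
    n = float(counts[index])
    return (m - n) / (m + n) if (m + n) > 0 else 0.0


def rank_variant(w: float, c: float, s: float) -> float:
    """Total voting rank 35*w + 90*c + 10*s with the printed weightings."""
    if w not in (0, 5, 10):
        raise ValidationError(f"class weight must be 0, 5 or 10, got {w}")
    if not 0.0 <= c <= 1.0:
        raise ValidationError(f"sequence concordance {c} outside [0, 1]")
    if not -1.0 <= s <= 1.0:
        raise ValidationError(f"bin representation score {s} outside [-1, 1]")
    return 35.0 * w + 90.0 * c + 10.0 * s


def resolve_duplicate_probes(ranked: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """One probe per variant: the higher-ranked probe wins; exact rank ties
    are broken by a seeded random draw (reproducible)."""
    rng = substream(seed, "duplicate-probes")
    out_rows = []
    for vid, grp in ranked.groupby("variant_id", sort=True):
        top = grp[grp["rank"] == grp["rank"].max()]
        if len(top) == 1:
            out_rows.append(top.index[0])
        else:
            out_rows.append(rng.choice(top.index.to_numpy()))
    return ranked.loc[sorted(out_rows)].reset_index(drop=True)


@dataclass
class ArrayDesign:
    """Selected array content plus composition counts."""

    variants: pd.DataFrame  # variant_id, rank, route, plus carried columns
    composition: dict = field(default_factory=dict)


def assemble_final(
    forwarded_phr: list,
    forwarded_otv: list,
    ranked: pd.DataFrame,
    target_size: int,
    seed: int = 0,
) -> ArrayDesign:
    """Fill the array: forwarded sets unconditionally, then the ranked
    remainder by descending rank (ties in seeded order) up to
    ``target_size``."""
    forwarded = list(dict.fromkeys(list(forwarded_phr) + list(forwarded_otv)))
    if target_size < len(forwarded):
        raise ValidationError(
            f"target size {target_size} below forwarded set of {len(forwarded)}"
        )
    phr_set = set(forwarded_phr)
    rows = [
        {"variant_id": vid, "rank": np.nan,
         "route": "forwarded-PHR" if vid in phr_set else "forwarded-OTV"}
        for vid in forwarded
    ]
    remainder = ranked[~ranked["variant_id"].isin(set(forwarded))].copy()
    rng = substream(seed, "final-ranking")
    remainder["_tiebreak"] = rng.random(len(remainder))
    remainder = remainder.sort_values(
        ["rank", "_tiebreak"], ascending=[False, True], kind="stable"
    )
    n_fill = target_size - len(forwarded)
    if n_fill > len(remainder):
        warnings.warn(
            f"target size {target_size} exceeds candidate pool "
            f"({len(forwarded) + len(remainder)}); returning all candidates"
        )
        n_fill = len(remainder)
    take = remainder.head(n_fill)
    rows.extend(
        {"variant_id": r.variant_id, "rank": r.rank, "route": "ranked"}
        for r in take.itertuples()
    )
    design = pd.DataFrame(rows, columns=["variant_id", "rank", "route"])
    if design["variant_id"].duplicated().any():
        raise ValidationError("duplicate variant ids in assembled design")
    composition = {
        "n_total": int(len(design)),
        "n_forwarded_phr": int(len(forwarded_phr)),
        "n_forwarded_otv": int(len(set(forwarded_otv) - phr_set)),
        "n_ranked": int(len(take)),
    }
    return ArrayDesign(design, composition)


# ---------------------------------------------------------------------------
# annotation and density
# ---------------------------------------------------------------------------


def _gene_trees(genes: pd.DataFrame):
    """Per-chromosome interval trees for gene bodies and, when a feature
    column is available, for exon/CDS and UTR features."""
    has_features = "feature" in genes.columns
    gene_rows = genes[genes["feature"] == "gene"] if has_features else genes
    body = {}
    for chrom, sub in gene_rows.groupby("chrom"):
        tree = IntervalTree()
        for r in sub.itertuples():
            if r.end < r.start:
                raise ValidationError(f"malformed interval for gene {r.gene_id}")
            tree[r.start: r.end + 1] = (r.gene_id, r.strand)
        body[chrom] = tree
    feats: dict = {}
    if has_features:
        for chrom, sub in genes[genes["feature"] != "gene"].groupby("chrom"):
            tree = IntervalTree()
            for r in sub.itertuples():
                kind = "UTR" if "UTR" in r.feature else "coding"
                tree[r.start: r.end + 1] = (r.gene_id, kind)
            feats[chrom] = tree
    return body, feats, has_features


def annotate_variants(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 5_000,
) -> tuple[pd.DataFrame, dict]:
    """Label each variant against the gene models and summarize gene
    tagging.

    With feature-level gene models (exon/CDS/UTR rows) the labels are
    coding / UTR / intron; with plain gene intervals the three collapse to
    'genic' and the summary notes it.  Variants within ``flank`` bp of a
    gene (strand-aware) get upstream-5kb / downstream-5kb labels; anything
    else is intergenic.  The summary reports genes tagged at both
    stringencies (gene body only, and including flanks) over the gene
    universe.
    """
    body, feats, has_features = _gene_trees(genes)
    gene_ids = (
        genes.loc[genes["feature"] == "gene", "gene_id"]
        if has_features
        else genes["gene_id"]
    ).unique()
    strict_tagged: set = set()
    flank_tagged: set = set()
    labels = []
    for r in variants.itertuples():
        pos = int(r.pos)
        chrom = r.chrom
        var_labels: list[str] = []
        hits = body.get(chrom, IntervalTree())[pos]
        for hit in hits:
            gid = hit.data[0]
            strict_tagged.add(gid)
            flank_tagged.add(gid)
            if has_features:
                fhits = {d.data[1] for d in feats.get(chrom, IntervalTree())[pos]
                         if d.data[0] == gid}
                if "coding" in fhits:
                    var_labels.append("coding")
                elif "UTR" in fhits:
                    var_labels.append("UTR")
                else:
                    var_labels.append("intron")
            else:
                var_labels.append("genic")
        if not hits:
            near = body.get(chrom, IntervalTree())[max(1, pos - flank): pos + flank + 1]
            for hit in near:
                gid, strand = hit.data
                flank_tagged.add(gid)
                start, end = hit.begin, hit.end - 1
                if pos < start:
                    var_labels.append(
                        "upstream-5kb" if strand == "+" else "downstream-5kb"
                    )
                elif pos > end:
                    var_labels.append(
                        "downstream-5kb" if strand == "+" else "upstream-5kb"
                    )
        if not var_labels:
            var_labels = ["intergenic"]
        labels.append(",".join(sorted(set(var_labels))))
    table = variants[["variant_id", "chrom", "pos"]].copy()
    table["labels"] = labels
    n_genes = len(gene_ids)
    summary = {
        "n_genes": int(n_genes),
        "genes_tagged_genic": int(len(strict_tagged)),
        "genes_tagged_with_flanks": int(len(flank_tagged)),
        "pct_tagged_genic": 100.0 * len(strict_tagged) / n_genes if n_genes else 0.0,
        "pct_tagged_with_flanks": 100.0 * len(flank_tagged) / n_genes if n_genes else 0.0,
        "feature_resolution": "coding/intron/UTR" if has_features else "genic-only",
    }
    return table, summary


def density_stats(
    variants: pd.DataFrame,
    chrom_lengths: dict[str, int],
    genetic_map: pd.DataFrame | None = None,
) -> dict:
    """Marker-spacing summary.

    Reports the genome-average density (genome size / variant count, in kb
    per variant) and per-chromosome plus overall mean/median/max neighbor
    gaps in kb.  With a genetic map (columns chrom, pos, cm) the mean cM
    gap is computed by linear interpolation of map positions (constant
    extrapolation beyond the anchors).
    """
    if len(variants) == 0:
        raise ValidationError("design is empty")
    gaps_all = []
    per_chrom = {}
    cm_gaps = []
    for chrom, sub in variants.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy())
        gaps = np.diff(pos)
        if gaps.size:
            gaps_all.append(gaps)
            per_chrom[chrom] = {
                "n": int(pos.size),
                "mean_kb": float(gaps.mean() / 1e3),
                "median_kb": float(np.median(gaps) / 1e3),
                "max_kb": float(gaps.max() / 1e3),
            }
        if genetic_map is not None:
            anchors = genetic_map[genetic_map["chrom"] == chrom].sort_values("pos")
            if len(anchors) >= 2:
                cm = np.interp(pos, anchors["pos"], anchors["cm"])
                cm_gaps.append(np.diff(cm))
    gaps_all = np.concatenate(gaps_all) if gaps_all else np.array([])
    genome_size = float(sum(chrom_lengths.values()))
    out = {
        "n_variants": int(len(variants)),
        "genome_size_bp": genome_size,
        "mean_density_kb": genome_size / len(variants) / 1e3,
        "per_chromosome": per_chrom,
    }
    if gaps_all.size:
        out.update(
            mean_gap_kb=float(gaps_all.mean() / 1e3),
            median_gap_kb=float(np.median(gaps_all) / 1e3),
            max_gap_kb=float(gaps_all.max() / 1e3),
        )
    if cm_gaps:
        cm_all = np.concatenate(cm_gaps)
        out["mean_gap_cm"] = float(cm_all.mean())
    return out
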