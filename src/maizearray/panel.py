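"""Validation-panel analyses: replicate concordance, trio Mendelian
checks, polymorphism partition, MAF spectra, Rogers-distance PCoA, LD
statistics, pruning, decay estimation, and mode imputation.

Genotype matrices are samples x variants with sequencing-space codes
(hom-ref = 0, het = 1, hom-alt = 2, missing = -1); indels are treated as
bi-allelic SNPs throughout.  For off-target variants the presence/absence
of the flanking variant can be carried as an auxiliary bi-allelic matrix
and analyzed like any other marker set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .containers import HET, HOM_ALT, HOM_REF, MISSING
from .errors import ValidationError

__all__ = [
    "replicate_concordance",
    "trio_mendelian",
    "polymorphism_partition",
    "maf_spectrum",
    "MafSpectrum",
    "rogers_distance",
    "pcoa",
    "PcoaResult",
    "ld_r2",
    "ld_decay_distance",
    "ld_prune",
    "impute_missing",
]


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValidationError("genotype matrix must be 2-D (samples x variants)")
    return m


def replicate_concordance(matrix: np.ndarray, pairs: list[tuple[int, int]]) -> pd.DataFrame:
    """Percent identical calls per replicate pair over loci where both
    members are called; ``nan`` (flagged) when no locus is comparable."""
    m = _check_matrix(matrix)
    rows = []
    for i, j in pairs:
        both = (m[i] != MISSING) & (m[j] != MISSING)
        n = int(both.sum())
        pct = 100.0 * float((m[i][both] == m[j][both]).mean()) if n else float("nan")
        rows.append((i, j, n, pct, n == 0))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "n_comparable", "pct_identical", "undefined"]
    )


# offspring genotype o is Mendelian-consistent with parents (a, b) iff one
# allele can come from each parent
_ALLELES = {HOM_REF: (0,), HET: (0, 1), HOM_ALT: (1,)}
_CONSISTENT = np.zeros((3, 3, 3), dtype=bool)
for _a in range(3):
    for _b in range(3):
        for _o in range(3):
            _CONSISTENT[_a, _b, _o] = any(
                x + y == _o for x in _ALLELES[_a] for y in _ALLELES[_b]
            )


def trio_mendelian(
    matrix: np.ndarray, trios: list[tuple[int, int, int]]
) -> tuple[float, pd.DataFrame]:
    """Mendelian consistency of (offspring, parent1, parent2) trios.

    A variant is consistent for a trio iff the offspring call is compatible
    with one transmitted allele from each parent; variants with any missing
    member are skipped for that trio.  Returns the percentage of variants
    consistent across all evaluated trios, plus per-trio rates.
    """
    m = _check_matrix(matrix)
    n_var = m.shape[1]
    all_ok = np.ones(n_var, dtype=bool)
    evaluated = np.zeros(n_var, dtype=bool)
    rows = []
    for off, p1, p2 in trios:
        for idx in (off, p1, p2):
            if not 0 <= idx < m.shape[0]:
                raise ValidationError(f"trio sample index {idx} out of range")
        usable = (m[off] != MISSING) & (m[p1] != MISSING) & (m[p2] != MISSING)
        ok = np.ones(n_var, dtype=bool)
        ok[usable] = _CONSISTENT[m[p1][usable], m[p2][usable], m[off][usable]]
        all_ok &= ok
        evaluated |= usable
        n_use = int(usable.sum())
        rate = 100.0 * float(ok[usable].mean()) if n_use else float("nan")
        rows.append((off, p1, p2, n_use, rate))
    per_trio = pd.DataFrame(
        rows, columns=["offspring", "parent1", "parent2", "n_variants", "pct_consistent"]
    )
    n_eval = int(evaluated.sum())
    overall = 100.0 * float(all_ok[evaluated].mean()) if n_eval else float("nan")
    return overall, per_trio


def polymorphism_partition(
    matrix: np.ndarray, groups: dict[str, list[int]]
) -> tuple[dict, dict]:
    """Per-group polymorphism and the Venn decomposition.

    A variant is polymorphic within a group iff at least two distinct
    non-missing genotypes occur among its members.  Returns
    (per-group summary, venn) where venn maps a frozenset of group names to
    the number of variants polymorphic in exactly those groups.
    """
    m = _check_matrix(matrix)
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValidationError("groups must be non-empty")
    poly = {}
    for name, idx in groups.items():
        sub = m[np.asarray(idx)]
        n_distinct = np.zeros(m.shape[1], dtype=int)
        for g in (HOM_REF, HET, HOM_ALT):
            n_distinct += (sub == g).any(axis=0)
        poly[name] = n_distinct >= 2
    summary = {
        name: {
            "n_polymorphic": int(mask.sum()),
            "pct_polymorphic": 100.0 * float(mask.mean()),
        }
        for name, mask in poly.items()
    }
    names = list(groups)
    venn: dict = {}
    for bits in range(1, 2 ** len(names)):
        inset = frozenset(n for k, n in enumerate(names) if bits >> k & 1)
        mask = np.ones(m.shape[1], dtype=bool)
        for n in names:
            mask &= poly[n] if n in inset else ~poly[n]
        venn[inset] = int(mask.sum())
    return summary, venn


@dataclass
class MafSpectrum:
    maf: np.ndarray
    hist: np.ndarray
    bin_edges: np.ndarray
    frac_below_005: float


def maf_spectrum(
    matrix: np.ndarray,
    subset: np.ndarray | None = None,
    bins: np.ndarray | None = None,
) -> MafSpectrum:
    """Minor-allele-frequency histogram.

    Per variant, the alt-allele frequency p is computed from non-missing
    calls (a het contributes half); MAF = min(p, 1 - p).  ``subset`` is an
    optional variant index/mask (e.g. the flanking-OTV markers).
    """
    m = _check_matrix(matrix)
    if subset is not None:
        m = m[:, np.asarray(subset)]
    bins = np.arange(0.0, 0.525, 0.025) if bins is None else np.asarray(bins)
    called = m != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(m == HOM_ALT, 2, 0) + np.where(m == HET, 1, 0)
    with np.errstate(invalid="ignore"):
        p = alt.sum(axis=0) / (2.0 * np.maximum(n_called, 1))
    p = np.where(n_called > 0, p, np.nan)
    maf = np.minimum(p, 1.0 - p)
    valid = ~np.isnan(maf)
    hist, edges = np.histogram(maf[valid], bins=bins)
    frac = float((maf[valid] < 0.05).mean()) if valid.any() else float("nan")
    return MafSpectrum(maf, hist, edges, frac)


def rogers_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Rogers' distances between samples.

    Per bi-allelic locus the two genotypes define allele-frequency vectors
    ((1,0), (0.5,0.5), (0,1)); the locus distance
    sqrt(0.5 * sum (p - q)^2) reduces to |p_alt - q_alt|, and the sample
    distance is the mean over loci called in both samples.  Output is a
    symmetric matrix in [0, 1] with zero diagonal; pairs with no shared
    locus get ``nan``.
    """
    m = _check_matrix(matrix)
    if m.shape[0] < 2:
        raise ValidationError("at least 2 samples are required")
    p = np.where(m == MISSING, np.nan, m / 2.0)
    n = m.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(p[i] - p[i + 1:])
        shared = (~np.isnan(diff)).sum(axis=1)
        total = np.nansum(diff, axis=1)
        row = np.where(shared > 0, total / np.maximum(shared, 1), np.nan)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return d


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # (n_samples, n_axes)
    proportion_explained: np.ndarray


def pcoa(distances: np.ndarray, n_axes: int = 2) -> PcoaResult:
    """Principal coordinate analysis (classical metric scaling) of a
    symmetric distance matrix, axes ordered by eigenvalue."""
    d = np.asarray(distances, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    import warnings

    from skbio.stats.ordination import pcoa as _skbio_pcoa

    with warnings.catch_warnings():
        # full-dimension computation is intended; genetic distances are
        # generally non-Euclidean so mildly negative eigenvalues are expected
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(d, method="eigh", number_of_dimensions=0)
    coords = res.samples.to_numpy()
    prop = res.proportion_explained.to_numpy()
    if coords.shape[1] < n_axes:  # degenerate input: pad with zero axes
        pad = n_axes - coords.shape[1]
        coords = np.hstack([coords, np.zeros((coords.shape[0], pad))])
        prop = np.concatenate([prop, np.zeros(pad)])
    return PcoaResult(coords[:, :n_axes], prop[:n_axes])


def _dosage(matrix: np.ndarray) -> np.ndarray:
    return np.where(matrix == MISSING, np.nan, matrix.astype(float))


def _pair_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared correlation of two dosage vectors over pairwise-complete
    observations; nan for monomorphic or empty overlap."""
    both = ~np.isnan(a) & ~np.isnan(b)
    if both.sum() < 2:
        return float("nan")
    x, y = a[both], b[both]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_r2(
    matrix: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray | None = None,
    window_bp: int = 50_000_000,
) -> pd.DataFrame:
    """Pairwise r-squared between genotype dosages (0/1/2) for variant
    pairs within the same chromosome-wise window; monomorphic variants are
    excluded.  Returns a frame with columns i, j, dist_bp, r2."""
    m = _check_matrix(matrix)
    positions = np.asarray(positions)
    chroms = np.zeros(m.shape[1], dtype=int) if chroms is None else np.asarray(chroms)
    dose = _dosage(m)
    rows = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(positions[idx], kind="stable")]
        pos = positions[idx]
        win = (pos // window_bp).astype(int)
        for a_i in range(len(idx)):
            for b_i in range(a_i + 1, len(idx)):
                if win[b_i] != win[a_i]:
                    break
                r2 = _pair_r2(dose[:, idx[a_i]], dose[:, idx[b_i]])
                if not np.isnan(r2):
                    rows.append(
                        (int(idx[a_i]), int(idx[b_i]), int(pos[b_i] - pos[a_i]), r2)
                    )
    return pd.DataFrame(rows, columns=["i", "j", "dist_bp", "r2"])


def ld_decay_distance(
    dist_bp: np.ndarray,
    r2: np.ndarray,
    threshold: float = 0.2,
    bins_per_decade: int = 50,
    min_pairs: int = 20,
) -> float | None:
    """Distance (kb) at which the fitted r-squared decay crosses
    ``threshold``.

    Pairs are binned on a log-distance grid, bin means are made monotone
    non-increasing by isotonic regression, and the crossing is linearly
    interpolated between bin centers.  Returns 0.0 when the fitted curve is
    already below the threshold at the smallest distance and None
    (undefined) when it never crosses or fewer than ``min_pairs`` pairs are
    available.
    """
    dist_bp = np.asarray(dist_bp, float)
    r2 = np.asarray(r2, float)
    ok = (dist_bp > 0) & ~np.isnan(r2)
    dist_bp, r2 = dist_bp[ok], r2[ok]
    if dist_bp.size < min_pairs:
        return None
    log_d = np.log10(dist_bp)
    lo, hi = log_d.min(), log_d.max()
    n_bins = max(3, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(log_d, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            centers.append(log_d[mask].mean())
            means.append(r2[mask].mean())
    centers = np.asarray(centers)
    means = np.asarray(means)
    fitted = IsotonicRegression(increasing=False).fit_transform(centers, means)
    if fitted[0] <= threshold:
        return 0.0
    below = np.flatnonzero(fitted <= threshold)
    if below.size == 0:
        return None
    k = below[0]
    x0, x1 = centers[k - 1], centers[k]
    y0, y1 = fitted[k - 1], fitted[k]
    log_cross = x0 + (y0 - threshold) * (x1 - x0) / (y0 - y1) if y0 != y1 else x1
    return float(10 ** log_cross / 1e3)


def ld_prune(
    matrix: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray | None = None,
    r2_max: float = 0.8,
    window_bp: int = 50_000_000,
) -> np.ndarray:
    """Greedy left-to-right LD pruning: drop a variant whose r-squared with
    any retained variant in the same window exceeds ``r2_max``.
    Deterministic; returns the retained variant indices in genomic order."""
    m = _check_matrix(matrix)
    positions = np.asarray(positions)
    chroms = np.zeros(m.shape[1], dtype=int) if chroms is None else np.asarray(chroms)
    dose = _dosage(m)
    retained: list[int] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(positions[idx], kind="stable")]
        kept_here: list[int] = []
        for v in idx:
            win = positions[v] // window_bp
            conflict = any(
                positions[u] // window_bp == win
                and (_pair_r2(dose[:, v], dose[:, u]) or 0.0) > r2_max
                for u in kept_here
            )
            if not conflict:
                kept_here.append(int(v))
        retained.extend(kept_here)
    return np.asarray(retained, dtype=int)


def impute_missing(
    matrix: np.ndarray, max_missing_fraction: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Drop variants with at least ``max_missing_fraction`` missing calls,
    fill remaining missing values with the variant's most frequent genotype
    (ties resolved to the smaller code), deterministically.  Returns
    (completed matrix, retained variant indices)."""
    m = _check_matrix(matrix)
    miss_frac = (m == MISSING).mean(axis=0)
    keep = np.flatnonzero(miss_frac < max_missing_fraction)
    out = m[:, keep].copy()
    for col in range(out.shape[1]):
        colv = out[:, col]
        missing = colv == MISSING
        if not missing.any():
            continue
        counts = [(colv == g).sum() for g in (HOM_REF, HET, HOM_ALT)]
        colv[missing] = int(np.argmax(counts))
    return out, keep
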