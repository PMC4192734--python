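"""Bin-based screening-array candidate selection.

The genome is tiled into 100 kb bins; fixed content (coding variants and
legacy-array SNPs) is subtracted from the array capacity to give an average
per-bin budget (48 for the published capacity of 1.23 M probes over 20,660
bins).  Bins are filled from p-convert-categorized candidates in three
cases, with pool-frequency quotas (one third Flint-specific, one third
Dent-specific, one sixth common, one sixth rare for both pools) applied
whenever a draw is needed, and a 50 kb fill-up pass tops up sparse regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConfigurationError, ValidationError

__all__ = [
    "partition_bins",
    "compute_bin_budget",
    "classify_frequency",
    "assign_bins",
    "largest_remainder",
    "assemble_bin",
    "assemble_bins",
    "fillup_50kb",
    "build_screening_set",
    "DEFAULT_QUOTAS",
]

# quota cells keyed by (Dent class, Flint class); "specific for Flint" is the
# printed (Dent A | Flint B) convention even though the naming looks inverted
DEFAULT_QUOTAS = {
    ("A", "B"): 1 / 3,  # Flint-specific
    ("B", "A"): 1 / 3,  # Dent-specific
    ("A", "A"): 1 / 6,  # common
    ("B", "B"): 1 / 6,  # rare in both
}


def partition_bins(lengths: dict[str, int] | int, bin_width: int = 100_000) -> pd.DataFrame:
    """Tile chromosomes into fixed-width bins (0-based half-open starts).

    ``lengths`` may be a per-chromosome dict or a single aggregate genome
    size (tiled as one pseudo-chromosome, which reproduces the published
    20,660 bins for 2.066 Gb at 100 kb width).
    """
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    if isinstance(lengths, (int, np.integer)):
        lengths = {"genome": int(lengths)}
    rows = []
    bin_id = 0
    for chrom, length in lengths.items():
        if length <= 0:
            raise ConfigurationError(f"chromosome {chrom} has non-positive length")
        n = int(np.ceil(length / bin_width))
        for k in range(n):
            start = k * bin_width
            rows.append((bin_id, chrom, start, min(start + bin_width, length)))
            bin_id += 1
    return pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])


def compute_bin_budget(
    total_capacity: int = 1_230_000,
    fixed_coding: int = 150_394,
    fixed_legacy_probes: int = 2 * 48_324,
    n_bins: int = 20_660,
) -> int:
    """Average per-bin budget once the fixed content is subtracted."""
    for v in (total_capacity, fixed_coding, fixed_legacy_probes, n_bins):
        if v < 0:
            raise ConfigurationError("counts must be non-negative")
    free = total_capacity - fixed_coding - fixed_legacy_probes
    if free < 0:
        raise ConfigurationError("capacity smaller than the fixed variant set")
    return int(round(free / n_bins))


def classify_frequency(freq) -> str | None:
    """Pool allele-frequency class: 'A' for intermediate (0.2 <= f <= 0.8),
    'B' for extreme (< 0.2 or > 0.8); undefined (None/nan) propagates."""
    if freq is None:
        return None
    f = float(freq)
    if np.isnan(f):
        return None
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"frequency {f} outside [0, 1]")
    return "A" if 0.2 <= f <= 0.8 else "B"


def assign_bins(positions: pd.DataFrame, bin_width: int = 100_000) -> np.ndarray:
    """Map 1-based positions to per-chromosome bin indices ``(pos-1)//width``."""
    return ((positions["pos"].to_numpy() - 1) // bin_width).astype(int)


def largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Hamilton apportionment of ``total`` among cells with given fractions."""
    quotas = total * np.asarray(fractions, float)
    base = np.floor(quotas).astype(int)
    remainder = total - base.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:remainder]] += 1
    return base


def _quota_draw(
    pool: pd.DataFrame, k: int, quotas: dict, rng: np.random.Generator, log: list
) -> list:
    """Seeded quota draw of ``k`` candidates from ``pool`` (columns
    dent_class, flint_class).  Shortfall in an exhausted cell is
    redistributed proportionally to the remaining cells (largest-remainder
    on the renormalized quotas) and logged."""
    cells = list(quotas)
    members = {
        c: pool.index[(pool["dent_class"] == c[0]) & (pool["flint_class"] == c[1])].to_numpy()
        for c in cells
    }
    target = dict(zip(cells, largest_remainder(k, np.array([quotas[c] for c in cells]))))
    chosen: list = []
    open_cells = list(cells)
    while True:
        shortfall = 0
        for c in list(open_cells):
            avail = members[c]
            take = min(target[c], avail.size)
            if take:
                picked = rng.choice(avail, size=take, replace=False)
                chosen.extend(picked.tolist())
                members[c] = np.setdiff1d(avail, picked, assume_unique=True)
            if target[c] > take:
                shortfall += target[c] - take
                log.append(f"cell {c}: short by {target[c] - take}")
                open_cells.remove(c)
            target[c] = 0
        if shortfall == 0 or not open_cells:
            break
        weights = np.array([quotas[c] for c in open_cells], float)
        redistributed = largest_remainder(shortfall, weights / weights.sum())
        for c, extra in zip(open_cells, redistributed):
            target[c] = int(extra)
    return chosen


def assemble_bin(
    candidates: pd.DataFrame,
    budget: int = 48,
    quotas: dict | None = None,
    rng: np.random.Generator | None = None,
    log: list | None = None,
) -> list:
    """Select candidate row-indices for one bin.

    Case (i): all 'recommended'+'neutral' candidates when fewer than the
    budget exist.  Case (ii): all 'recommended' fixed, remainder quota-drawn
    from 'neutral'.  Case (iii): budget quota-drawn from 'recommended' when
    they alone reach the budget.
    """
    if budget < 0:
        raise ConfigurationError("budget must be non-negative")
    quotas = quotas or DEFAULT_QUOTAS
    rng = rng or np.random.default_rng(0)
    log = log if log is not None else []
    rec = candidates[candidates["pconvert_category"] == "recommended"]
    neu = candidates[candidates["pconvert_category"] == "neutral"]
    if len(rec) + len(neu) < budget:
        return rec.index.tolist() + neu.index.tolist()
    if len(rec) >= budget:
        return _quota_draw(rec, budget, quotas, rng, log)
    return rec.index.tolist() + _quota_draw(neu, budget - len(rec), quotas, rng, log)


def assemble_bins(
    candidates: pd.DataFrame,
    bin_width: int = 100_000,
    budget: int = 48,
    quotas: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Apply :func:`assemble_bin` across all (chrom, bin) groups.

    ``candidates`` needs columns chrom, pos, pconvert_category, dent_class,
    flint_class.  Returns the selected rows and the shortfall log.
    """
    log: list = []
    bins = assign_bins(candidates, bin_width)
    selected: list = []
    work = candidates.assign(_bin=bins)
    for i, ((chrom, b), grp) in enumerate(work.groupby(["chrom", "_bin"], sort=True)):
        rng = substream(seed, "bin-assembly", i)
        sub_log: list = []
        selected.extend(assemble_bin(grp, budget, quotas, rng, sub_log))
        log.extend(f"{chrom}:{b}: {msg}" for msg in sub_log)
    return candidates.loc[sorted(selected)], log


def fillup_50kb(
    candidates: pd.DataFrame,
    selected_ids: set,
    bin_width_100kb: int = 100_000,
    budget_100kb: int = 48,
    threshold: int = 8,
    balanced_cap: int = 6,
    hom_ref_min: int = 6,
    hom_ref_max_exclusive: int = 22,
    min_called_lines: int = 28,
    seed: int = 0,
) -> list:
    """50 kb fill-up pass for under-filled 100 kb bins.

    For each 100 kb bin holding fewer than ``budget_100kb`` selections, each
    50 kb half with fewer than ``threshold`` selected variants is topped up:
    first (at most ``balanced_cap`` picks) from 'recommended' candidates with
    at least ``min_called_lines`` called lines and a hom-ref call count in
    [``hom_ref_min``, ``hom_ref_max_exclusive``), then from any remaining
    candidates, until the half holds ``threshold`` or candidates run out.
    Returns the variant_ids added.
    """
    half = bin_width_100kb // 2
    work = candidates.assign(
        _bin100=assign_bins(candidates, bin_width_100kb),
        _bin50=assign_bins(candidates, half),
    )
    added: list = []
    chosen = set(selected_ids)
    groups = work.groupby(["chrom", "_bin100"], sort=True)
    for i, ((chrom, b100), grp) in enumerate(groups):
        n_sel_100 = grp["variant_id"].isin(chosen).sum()
        if n_sel_100 >= budget_100kb:
            continue
        rng = substream(seed, "fillup-50kb", i)
        for b50, half_grp in grp.groupby("_bin50", sort=True):
            in_sel = half_grp["variant_id"].isin(chosen)
            n_have = int(in_sel.sum())
            if n_have >= threshold:
                continue
            avail = half_grp[~in_sel]
            balanced = avail[
                (avail["pconvert_category"] == "recommended")
                & (avail["called_lines"] >= min_called_lines)
                & (avail["hom_ref_calls"] >= hom_ref_min)
                & (avail["hom_ref_calls"] < hom_ref_max_exclusive)
            ]
            n_bal = min(balanced_cap, threshold - n_have, len(balanced))
            picks = (
                rng.choice(balanced["variant_id"].to_numpy(), n_bal, replace=False).tolist()
                if n_bal else []
            )
            n_have += len(picks)
            rest = avail[~avail["variant_id"].isin(picks)]
            n_more = min(threshold - n_have, len(rest))
            if n_more > 0:
                picks += rng.choice(rest["variant_id"].to_numpy(), n_more,
                                    replace=False).tolist()
            chosen.update(picks)
            added.extend(picks)
    return added


def build_screening_set(
    coding_candidates: pd.DataFrame,
    legacy_candidates: pd.DataFrame,
    binned_selection: pd.DataFrame,
    target: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the screening list from the three sources.

    Coding variants enter unless 'not possible', keeping the higher-p-convert
    probe when two probes exist; legacy-array SNPs contribute both probe sets
    (forward and reverse) unless a probe is 'not possible'; novel binned
    candidates must be 'recommended' or 'neutral' and unique.
    Returns the combined probe table plus per-source counts.
    """
    coding = coding_candidates[coding_candidates["pconvert_category"] != "not possible"]
    coding = (
        coding.sort_values("pconvert", ascending=False, kind="stable")
        .drop_duplicates("variant_id", keep="first")
        .assign(origin="coding")
    )
    legacy = legacy_candidates[
        legacy_candidates["pconvert_category"] != "not possible"
    ].assign(origin="legacy-array")
    novel = binned_selection[
        binned_selection["pconvert_category"].isin(["recommended", "neutral"])
    ].assign(origin="novel")
    if novel["variant_id"].duplicated().any():
        raise ValidationError("duplicate novel variant ids in binned selection")
    overlap = set(novel["variant_id"]) & (set(coding["variant_id"]) | set(legacy["variant_id"]))
    if overlap:
        raise ValidationError(f"novel ids duplicate fixed content: {sorted(overlap)[:5]}")
    out = pd.concat([coding, legacy, novel], ignore_index=True)
    counts = {
        "coding": int(len(coding)),
        "legacy_probes": int(len(legacy)),
        "legacy_snps": int(legacy["variant_id"].nunique()),
        "novel": int(len(novel)),
        "total_probes": int(len(out)),
    }
    if target is not None:
        counts["target"] = int(target)
        counts["shortfall"] = int(max(0, target - len(out)))
    return out, counts
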