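"""Seeded synthetic genomes, panels, sequencing calls and intensity clouds.

The generator emulates the statistical structure of a multi-pool temperate
maize panel: two diverged germplasm pools (Dent, Flint) with pool-structured
allele frequencies, highly inbred lines with residual heterozygosity, F1
hybrids from known parents, technical replicates, paralog-confounded sites
that emit spurious heterozygous sequencing calls, and two-channel probe
intensities with planted cluster geometries including off-target-variant
(OTV) subpopulations.  Every downstream stage of the pipeline can therefore
be tested against planted truth without any external data.

All randomness flows from one top-level seed via named substreams
(:mod:`maizearray._rng`), so identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import HOM_REF, HET, HOM_ALT, VariantCallSet
from .errors import ConfigurationError

POOLS = ("Dent", "Flint", "admixed", "hybrid", "outgroup")

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@dataclass
class GenomeConfig:
    """Settings for :func:`simulate_genome`.

    ``chrom_lengths`` maps chromosome id to length in bp.  When
    ``telomere_gradient`` is on, the relative polymorphism rate rises
    quadratically from the chromosome center towards the ends (centromeric
    depletion as seen in real maize variant densities).  ``masked`` intervals
    (1-based inclusive) produce zero variants, emulating the variant-free
    nucleolus organizer region on chromosome 6S.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 2_400_000}
    )
    n_genes: int = 120
    gene_length: tuple[int, int] = (1_500, 6_000)
    telomere_gradient: bool = True
    gradient_strength: float = 3.0
    rate_window: int = 10_000
    masked: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class GenomeModel:
    """A toy genome: chromosome lengths, gene intervals, rate profiles.

    ``rate_profiles[chrom]`` holds one relative polymorphism rate per
    ``window``-sized slice of the chromosome (last slice truncated).
    ``genes`` has 1-based inclusive start/end coordinates.
    """

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame
    rate_profiles: dict[str, np.ndarray]
    window: int
    masked: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))


def simulate_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Build a seeded :class:`GenomeModel` from ``config``."""
    config = config or GenomeConfig()
    if not config.chrom_lengths:
        raise ConfigurationError("at least one chromosome is required")
    for chrom, length in config.chrom_lengths.items():
        if length <= 0:
            raise ConfigurationError(f"chromosome {chrom} has non-positive length {length}")

    rng = substream(seed, "genome")
    rate_profiles: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        n_win = int(np.ceil(length / config.rate_window))
        centers = (np.arange(n_win) + 0.5) / n_win
        if config.telomere_gradient:
            rate = 1.0 + config.gradient_strength * (2.0 * np.abs(centers - 0.5)) ** 2
        else:
            rate = np.ones(n_win)
        if chrom in config.masked:
            lo, hi = config.masked[chrom]
            win_start = np.arange(n_win) * config.rate_window + 1
            win_end = np.minimum(win_start + config.rate_window - 1, length)
            rate[(win_start <= hi) & (win_end >= lo)] = 0.0
        rate_profiles[chrom] = rate

    # place genes uniformly, proportional to chromosome length
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], float)
    counts = rng.multinomial(config.n_genes, lengths / lengths.sum())
    rows = []
    gid = 0
    for chrom, n in zip(chroms, counts):
        clen = config.chrom_lengths[chrom]
        for _ in range(n):
            glen = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
            glen = min(glen, clen)
            start = int(rng.integers(1, clen - glen + 2))
            rows.append((f"gene{gid:05d}", chrom, start, start + glen - 1,
                         "+" if rng.random() < 0.5 else "-"))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return GenomeModel(dict(config.chrom_lengths), genes, rate_profiles,
                       config.rate_window, dict(config.masked))


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


@dataclass
class SampleSpec:
    """One panel member.

    ``inbreeding`` is Wright's f in [0, 1]; ``inbred_penalty`` is the 0-16
    genotype-calling penalty (0 for F1 hybrids, 12 for inbreds with unclear
    homozygosity, 14 for pure inbreds and doubled haploids).  Hybrids carry
    the ids of their two parents; replicates reference their source sample.
    """

    id: str
    pool: str = "Dent"
    subgroup: str = ""
    inbreeding: float = 0.95
    inbred_penalty: int = 14
    replicate_of: str | None = None
    parents: tuple[str, str] | None = None


@dataclass
class PanelConfig:
    """Panel composition plus the allele-frequency model.

    Per-variant base frequencies are drawn from Beta(``beta_a``, ``beta_b``);
    pool divergence shifts the Dent and Flint frequencies symmetrically apart
    by ``divergence`` (direction randomized per variant).  Admixed samples
    mix the two pool frequencies with a per-sample weight.
    """

    samples: list[SampleSpec]
    beta_a: float = 0.4
    beta_b: float = 0.4
    divergence: float = 0.3
    mono_fraction: float = 0.05
    het_only_fraction: float = 0.05
    otv_fraction: float = 0.075
    indel_fraction: float = 0.011

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate sample ids in panel")
        known = set(ids)
        for s in self.samples:
            if s.pool not in POOLS:
                raise ConfigurationError(f"unknown pool {s.pool!r} for sample {s.id}")
            if s.pool == "hybrid":
                if s.parents is None or len(s.parents) != 2:
                    raise ConfigurationError(f"hybrid {s.id} must reference two parents")
                for p in s.parents:
                    if p not in known:
                        raise ConfigurationError(f"hybrid {s.id}: parent {p} not in panel")
                if s.inbreeding != 0:
                    raise ConfigurationError(f"hybrid {s.id} must have inbreeding 0")
            if s.replicate_of is not None and s.replicate_of not in known:
                raise ConfigurationError(
                    f"replicate {s.id} references unknown sample {s.replicate_of}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]


def default_panel(
    n_dent: int = 12,
    n_flint: int = 12,
    n_admixed: int = 2,
    n_trios: int = 2,
    n_replicates: int = 1,
    **kwargs,
) -> PanelConfig:
    """A small panel mirroring the structure of a validation panel:
    two inbred pools, a few admixed lines, trios, and technical replicates."""
    samples: list[SampleSpec] = []
    for i in range(n_dent):
        samples.append(SampleSpec(f"D{i:03d}", "Dent", "BSSS" if i % 2 else "Iodent"))
    for i in range(n_flint):
        samples.append(SampleSpec(f"F{i:03d}", "Flint", "NorthernFlint"))
    for i in range(n_admixed):
        samples.append(SampleSpec(f"X{i:03d}", "admixed", "", 0.9, 12))
    for i in range(n_trios):
        p1, p2 = f"D{i:03d}", f"F{i:03d}"
        samples.append(
            SampleSpec(f"H{i:03d}", "hybrid", "", 0.0, 0, parents=(p1, p2))
        )
    for i in range(n_replicates):
        samples.append(SampleSpec(f"D{i:03d}rep", "Dent", "BSSS", 0.95, 14,
                                  replicate_of=f"D{i:03d}"))
    return PanelConfig(samples=samples, **kwargs)


def validation_panel(**kwargs) -> PanelConfig:
    """A 285-sample panel emulating an array-validation cohort: two large
    inbred pools with subgroups, tropical/admixed material, doubled
    haploids, two outgroup accessions, 23 parent-offspring trios plus four
    extra hybrids, and five replicate samples.

    Inbred penalties follow the convention 0 for F1 hybrids, 12 for inbreds
    with unclear homozygosity, 14 for pure inbreds and doubled haploids.
    """
    samples: list[SampleSpec] = []
    dent_sub = ["BSSS", "Iodent", "LSC", "nonBSSS"]
    for i in range(110):
        samples.append(SampleSpec(f"D{i:03d}", "Dent", dent_sub[i % 4], 0.95, 14))
    for i in range(114):
        sub = "NorthernFlint" if i % 2 else "nonNorthernFlint"
        samples.append(SampleSpec(f"F{i:03d}", "Flint", sub, 0.95, 14))
    for i in range(13):
        samples.append(SampleSpec(f"T{i:03d}", "admixed", "tropical", 0.9, 12))
    for i in range(10):
        samples.append(SampleSpec(f"DH{i:02d}", "Flint", "landraceDH", 1.0, 14))
    for i in range(4):
        samples.append(SampleSpec(f"U{i:02d}", "admixed", "", 0.9, 12))
    for i in range(2):
        samples.append(SampleSpec(f"TEO{i}", "outgroup", "teosinte", 0.9, 12))
    for i in range(23):
        samples.append(
            SampleSpec(f"H{i:03d}", "hybrid", "trio", 0.0, 0,
                       parents=(f"D{i:03d}", f"F{i:03d}"))
        )
    for i in range(4):
        samples.append(
            SampleSpec(f"HP{i:02d}", "hybrid", "proprietary", 0.0, 0,
                       parents=(f"D{i + 30:03d}", f"D{i + 40:03d}"))
        )
    for i in range(3):
        samples.append(SampleSpec(f"B37rep{i}", "Dent", "BSSS", 0.95, 14,
                                  replicate_of="D000"))
    samples.append(SampleSpec("DK105rep", "Flint", "NorthernFlint", 0.95, 14,
                              replicate_of="F001"))
    samples.append(SampleSpec("EP1rep", "Flint", "NorthernFlint", 0.95, 14,
                              replicate_of="F003"))
    return PanelConfig(samples=samples, **kwargs)


@dataclass
class SimulatedTruth:
    """Planted truth for a simulated panel.

    ``genotypes`` is samples x variants with sequencing-space codes.
    ``flank_carrier`` marks samples carrying the off-target flanking variant
    (nonzero only for OTV-flagged variants).  ``variants`` holds per-variant
    metadata: chrom, pos, ref, alt, is_indel, is_coding, is_mono, is_otv,
    p_dent, p_flint (true pool allele frequencies) and, once intensities are
    simulated, the planted cluster category.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    flank_carrier: np.ndarray
    samples: list[str]
    panel: PanelConfig

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _draw_positions(genome: GenomeModel, n_variants: int, rng: np.random.Generator):
    """Rate-profile-weighted unique positions, sorted by (chrom, pos)."""
    weights = []
    chroms = genome.chromosomes
    for chrom in chroms:
        weights.append(genome.rate_profiles[chrom].sum())
    weights = np.array(weights, float)
    if weights.sum() <= 0:
        raise ConfigurationError("genome rate profiles are all zero")
    counts = rng.multinomial(n_variants, weights / weights.sum())
    out_chrom, out_pos = [], []
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        rate = genome.rate_profiles[chrom]
        probs = rate / rate.sum()
        length = genome.chrom_lengths[chrom]
        positions: set[int] = set()
        while len(positions) < n:
            wins = rng.choice(len(rate), size=n - len(positions), p=probs)
            offs = rng.integers(0, genome.window, size=len(wins))
            pos = wins * genome.window + offs + 1
            positions.update(int(p) for p in pos[pos <= length])
        sel = sorted(positions)
        out_chrom.extend([chrom] * n)
        out_pos.extend(sel)
    return out_chrom, out_pos


def _genotype_probs(p: np.ndarray, f: float) -> np.ndarray:
    """Inbreeding-adjusted genotype probabilities, shape (n_variants, 3)."""
    het = 2.0 * p * (1.0 - p) * (1.0 - f)
    hom_alt = p * p + f * p * (1.0 - p)
    hom_ref = 1.0 - het - hom_alt
    return np.clip(np.stack([hom_ref, het, hom_alt], axis=1), 0.0, 1.0)


def simulate_panel(
    genome: GenomeModel,
    panel: PanelConfig,
    n_variants: int = 1000,
    seed: int = 0,
) -> SimulatedTruth:
    """Draw per-variant pool frequencies and per-sample genotypes.

    Individual genotypes follow the inbreeding model (heterozygote
    probability ``2p(1-p)(1-f)``); hybrids are formed by one gamete draw from
    each simulated parent, replicates copy their source exactly.
    """
    if n_variants < 1:
        raise ConfigurationError("n_variants must be >= 1")
    rng = substream(seed, "panel")

    chroms, positions = _draw_positions(genome, n_variants, rng)
    ref_idx = rng.integers(0, 4, n_variants)
    alt_shift = rng.integers(1, 4, n_variants)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]
    is_indel = rng.random(n_variants) < panel.indel_fraction
    alt = np.where(is_indel, np.char.add(alt, "T"), alt)

    # variant-role flags (mutually exclusive planted roles)
    u = rng.random(n_variants)
    is_mono = u < panel.mono_fraction
    is_het_only = (~is_mono) & (u < panel.mono_fraction + panel.het_only_fraction)
    is_otv = (~is_mono) & (~is_het_only) & (
        u < panel.mono_fraction + panel.het_only_fraction + panel.otv_fraction
    )

    # pool allele frequencies: shared Beta base, symmetric divergence shift
    p_base = rng.beta(panel.beta_a, panel.beta_b, n_variants)
    sign = np.where(rng.random(n_variants) < 0.5, 1.0, -1.0)
    half = panel.divergence / 2.0
    p_dent = np.clip(p_base + sign * half, 0.0, 1.0)
    p_flint = np.clip(p_base - sign * half, 0.0, 1.0)
    p_out = rng.beta(panel.beta_a, panel.beta_b, n_variants)
    p_dent[is_mono] = 0.0
    p_flint[is_mono] = 0.0
    p_out[is_mono] = 0.0

    samples = panel.samples
    n_samples = len(samples)
    gt = np.full((n_samples, n_variants), HOM_REF, dtype=np.int8)
    admix_w = {s.id: rng.uniform(0.25, 0.75) for s in samples if s.pool == "admixed"}

    order = {"Dent": 0, "Flint": 0, "admixed": 0, "outgroup": 0, "hybrid": 1}
    idx_of = {s.id: i for i, s in enumerate(samples)}
    # base samples first, then hybrids, then replicates
    for s in sorted(samples, key=lambda s: (s.replicate_of is not None, order[s.pool])):
        i = idx_of[s.id]
        if s.replicate_of is not None:
            gt[i] = gt[idx_of[s.replicate_of]]
            continue
        if s.pool == "hybrid":
            g1 = gt[idx_of[s.parents[0]]]
            g2 = gt[idx_of[s.parents[1]]]
            a1 = _gamete(g1, rng)
            a2 = _gamete(g2, rng)
            gt[i] = (a1 + a2).astype(np.int8)
            continue
        if s.pool == "Dent":
            p = p_dent
        elif s.pool == "Flint":
            p = p_flint
        elif s.pool == "admixed":
            w = admix_w[s.id]
            p = w * p_dent + (1.0 - w) * p_flint
        else:  # outgroup
            p = p_out
        probs = _genotype_probs(p, s.inbreeding)
        draw = rng.random(n_variants)
        gt[i] = np.int8(
            (draw >= probs[:, 0]).astype(np.int8)
            + (draw >= probs[:, 0] + probs[:, 1]).astype(np.int8)
        )
        if np.any(is_het_only):
            gt[i, is_het_only] = HOM_REF

    # het-only variants: alt allele present only in heterozygous state in a
    # few base samples (plants the NoMinorHom cluster geometry)
    base_rows = [idx_of[s.id] for s in samples
                 if s.pool != "hybrid" and s.replicate_of is None]
    for j in np.flatnonzero(is_het_only):
        k = int(rng.integers(3, min(9, len(base_rows)) + 1))
        carriers = rng.choice(base_rows, size=k, replace=False)
        gt[carriers, j] = HET
    # rebuild hybrids and replicates affected by the override
    for s in sorted(samples, key=lambda s: s.replicate_of is not None):
        i = idx_of[s.id]
        if s.pool == "hybrid":
            g1 = gt[idx_of[s.parents[0]], is_het_only]
            g2 = gt[idx_of[s.parents[1]], is_het_only]
            gt[i, is_het_only] = (_gamete(g1, rng) + _gamete(g2, rng)).astype(np.int8)
        elif s.replicate_of is not None:
            gt[i] = gt[idx_of[s.replicate_of]]

    # OTV flanking-variant carriers: dominant presence marker, inherited by
    # hybrids from either parent, shared by replicates.  Flanking variants
    # are not touched by any ascertainment step, so their frequencies come
    # from the same population Beta as ordinary variants.
    carrier = np.zeros((n_samples, n_variants), dtype=bool)
    otv_idx = np.flatnonzero(is_otv)
    if otv_idx.size:
        q = rng.beta(panel.beta_a, panel.beta_b, otv_idx.size)
        for col, qq in zip(otv_idx, q):
            carrier[base_rows, col] = rng.random(len(base_rows)) < qq
        for s in sorted(samples, key=lambda s: s.replicate_of is not None):
            i = idx_of[s.id]
            if s.pool == "hybrid":
                carrier[i, otv_idx] = (
                    carrier[idx_of[s.parents[0]], otv_idx]
                    | carrier[idx_of[s.parents[1]], otv_idx]
                )
            elif s.replicate_of is not None:
                carrier[i] = carrier[idx_of[s.replicate_of]]
        # an off-target cloud needs at least two carriers and two
        # non-carriers to exist as a distinct cluster
        counts = carrier[:, otv_idx].sum(axis=0)
        degenerate = (counts < 2) | (counts > n_samples - 2)
        if degenerate.any():
            bad = otv_idx[degenerate]
            is_otv[bad] = False
            carrier[:, bad] = False

    genes = genome.genes
    is_coding = np.zeros(n_variants, dtype=bool)
    for chrom, sub in genes.groupby("chrom"):
        in_chrom = np.array([c == chrom for c in chroms])
        if not in_chrom.any():
            continue
        pos = np.array(positions)[in_chrom]
        hit = np.zeros(pos.size, dtype=bool)
        for start, end in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            hit |= (pos >= start) & (pos <= end)
        is_coding[np.flatnonzero(in_chrom)] = hit

    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i:06d}" for i in range(n_variants)],
            "chrom": chroms,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "is_indel": is_indel,
            "is_coding": is_coding,
            "is_mono": is_mono,
            "is_het_only": is_het_only,
            "is_otv": is_otv,
            "p_dent": p_dent,
            "p_flint": p_flint,
        }
    )
    return SimulatedTruth(variants, gt, carrier, panel.sample_ids, panel)


def _gamete(gt_row: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele (0/1) per variant from a parental genotype row."""
    allele = (gt_row == HOM_ALT).astype(np.int8)
    het = gt_row == HET
    if het.any():
        allele[het] = rng.integers(0, 2, int(het.sum())).astype(np.int8)
    return allele


# ---------------------------------------------------------------------------
# sequencing calls
# ---------------------------------------------------------------------------


def simulate_sequencing_calls(
    truth: SimulatedTruth,
    mean_depth: float | dict[str, float] = 12.0,
    paralog_fraction: float = 0.1,
    genotype_error_rate: float = 0.0,
    het_inflation: float = 0.85,
    caller_disagreement: float = 0.02,
    multiallelic_fraction: float = 0.02,
    seed: int = 0,
) -> VariantCallSet:
    """Emit caller-style records for the panel in ``truth``.

    Paralog-confounded variants (a ``paralog_fraction`` share, recorded back
    into ``truth.variants['is_paralog']``) emit spurious heterozygous calls
    with probability ``het_inflation`` per line, carry genomic copy number
    >= 50 and an elevated MQ0 fraction — the signature that the second-round
    filters are designed to remove.  ``mean_depth`` may be a dict per sample
    id to model deep (50x) versus shallow (12x) lines.
    """
    if not 0.0 <= paralog_fraction <= 1.0:
        raise ConfigurationError("paralog_fraction must be in [0, 1]")
    rng = substream(seed, "sequencing")
    n_var = truth.n_variants
    n_smp = truth.n_samples

    if isinstance(mean_depth, dict):
        means = np.array([float(mean_depth.get(s, 12.0)) for s in truth.samples])
    else:
        means = np.full(n_smp, float(mean_depth))
    depths = rng.poisson(means[None, :], size=(n_var, n_smp)).astype(np.int32)

    gt = truth.genotypes.T.astype(np.int8).copy()  # sites x samples
    if genotype_error_rate > 0:
        err = rng.random(gt.shape) < genotype_error_rate
        shift = rng.integers(1, 3, size=gt.shape).astype(np.int8)
        gt[err] = (gt[err] + shift[err]) % 3

    is_paralog = rng.random(n_var) < paralog_fraction
    if is_paralog.any():
        rows = np.flatnonzero(is_paralog)
        flip = rng.random((rows.size, n_smp)) < het_inflation
        block = gt[rows]
        block[flip] = HET
        gt[rows] = block

    cn = np.where(is_paralog, rng.integers(50, 200, n_var), rng.integers(1, 5, n_var))
    mq0f = np.where(
        is_paralog, rng.uniform(0.06, 0.40, n_var), rng.uniform(0.0, 0.04, n_var)
    ).round(4)
    qual = np.round(rng.gamma(4.0, 150.0, n_var), 1)

    samtools = np.ones(n_var, dtype=bool)
    gatk = np.ones(n_var, dtype=bool)
    dis = rng.random(n_var) < caller_disagreement
    which = rng.random(n_var) < 0.5
    samtools[dis & which] = False
    gatk[dis & ~which] = False

    alt = truth.variants["alt"].to_numpy().astype(object)
    multi = rng.random(n_var) < multiallelic_fraction
    if multi.any():
        ref = truth.variants["ref"].to_numpy()
        for j in np.flatnonzero(multi):
            extra = rng.choice([b for b in "ACGT" if b != ref[j] and b != alt[j]])
            alt[j] = f"{alt[j]},{extra}"

    sites = pd.DataFrame(
        {
            "variant_id": truth.variants["variant_id"],
            "chrom": truth.variants["chrom"],
            "pos": truth.variants["pos"],
            "ref": truth.variants["ref"],
            "alt": alt,
            "vtype": np.where(truth.variants["is_indel"], "indel", "SNP"),
            "qual": qual,
            "dp": depths.sum(axis=1),
            "cn": cn,
            "mq0f": mq0f,
            "samtools_call": samtools,
            "gatk_call": gatk,
        }
    )
    truth.variants["is_paralog"] = is_paralog
    return VariantCallSet(sites, gt, depths, list(truth.samples))


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------


@dataclass
class ClusterGeometry:
    """Planted two-channel cluster geometry (log2 scale).

    Genotype clusters sit at contrast x = +/-``contrast_delta`` (AA/BB) and 0
    (AB), at size baseline ``size_baseline`` (AB raised by
    ``het_size_offset``); per-point noise is Gaussian in log space, i.e.
    lognormal on the raw channels.  OTV carriers collapse to a low-size
    cluster ``otv_size_drop`` below baseline.  A configurable share of
    variants is planted as failed geometries: ``other_fraction`` misplaced
    clusters (all centers shifted off zero contrast by ``misplaced_shift``;
    only variants showing all three genotype classes are eligible) and
    ``low_call_fraction`` variants where ``ambiguous_sample_fraction`` of the
    samples smear uniformly along the contrast axis and cannot be called
    confidently.
    """

    contrast_delta: float = 1.5
    size_baseline: float = 10.0
    het_size_offset: float = 0.3
    sd_x: float = 0.15
    sd_y: float = 0.15
    otv_size_drop: float = 3.0
    other_fraction: float = 0.05
    low_call_fraction: float = 0.05
    ambiguous_sample_fraction: float = 0.25
    misplaced_shift: float = 2.7


PLANTED_CATEGORIES = (
    "PolyHighResolution",
    "NoMinorHom",
    "MonoHighResolution",
    "OTV",
    "CallRateBelowThreshold",
    "Other",
)


def simulate_intensities(
    truth: SimulatedTruth,
    geometry: ClusterGeometry | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a long two-channel intensity table (variant_id, sample_id,
    signal_A, signal_B) and record each variant's planted category in
    ``truth.variants['planted_category']``.

    Categories are planted consistently with the genotype truth: genuinely
    monomorphic variants become MonoHighResolution, variants whose minor
    allele occurs only in heterozygotes become NoMinorHom, OTV-flagged
    variants place their carriers in a low-size cluster, and a seeded share
    of the remaining polymorphic variants is degraded into
    CallRateBelowThreshold or Other geometries.
    """
    geom = geometry or ClusterGeometry()
    rng = substream(seed, "intensities")
    n_var, n_smp = truth.n_variants, truth.n_samples
    gt = truth.genotypes  # samples x variants

    n_hom_ref = (gt == HOM_REF).sum(axis=0)
    n_het = (gt == HET).sum(axis=0)
    n_hom_alt = (gt == HOM_ALT).sum(axis=0)
    n_classes = (
        (n_hom_ref > 0).astype(int) + (n_het > 0).astype(int) + (n_hom_alt > 0).astype(int)
    )
    minor_hom_absent = (n_hom_ref == 0) | (n_hom_alt == 0)

    planted = np.empty(n_var, dtype=object)
    u = rng.random(n_var)
    for j in range(n_var):
        if truth.variants["is_otv"].iat[j]:
            planted[j] = "OTV"
        elif n_classes[j] <= 1 and n_het[j] == 0:
            planted[j] = "MonoHighResolution"
        elif n_classes[j] == 3 and u[j] < geom.other_fraction:
            planted[j] = "Other"
        elif u[j] < geom.other_fraction + geom.low_call_fraction:
            planted[j] = "CallRateBelowThreshold"
        elif minor_hom_absent[j] and n_het[j] > 0:
            planted[j] = "NoMinorHom"
        else:
            planted[j] = "PolyHighResolution"

    d, y0, off = geom.contrast_delta, geom.size_baseline, geom.het_size_offset
    center_x = np.array([d, 0.0, -d])  # indexed by genotype code 0/1/2
    center_y = np.array([y0, y0 + off, y0])

    x = center_x[gt] + rng.normal(0.0, geom.sd_x, (n_smp, n_var))
    y = center_y[gt] + rng.normal(0.0, geom.sd_y, (n_smp, n_var))

    for j in range(n_var):
        cat = planted[j]
        if cat == "OTV":
            car = truth.flank_carrier[:, j]
            x[car, j] = 0.0 + rng.normal(0.0, geom.sd_x, int(car.sum()))
            y[car, j] = y0 - geom.otv_size_drop + rng.normal(0.0, geom.sd_y, int(car.sum()))
        elif cat == "Other":
            # misplace every cluster off zero contrast (HomRO failure)
            x[:, j] += geom.misplaced_shift
        elif cat == "CallRateBelowThreshold":
            amb = rng.random(n_smp) < geom.ambiguous_sample_fraction
            k = int(amb.sum())
            x[amb, j] = rng.uniform(-(d + 0.5), d + 0.5, k)
            y[amb, j] = y0 + rng.normal(0.0, 4.0 * geom.sd_y, k)

    truth.variants["planted_category"] = planted

    log_a = y + x / 2.0
    log_b = y - x / 2.0
    vids = truth.variants["variant_id"].to_numpy()
    table = pd.DataFrame(
        {
            "variant_id": np.repeat(vids, n_smp),
            "sample_id": np.tile(np.array(truth.samples, dtype=object), n_var),
            "signal_A": np.power(2.0, log_a.T).ravel(),
            "signal_B": np.power(2.0, log_b.T).ravel(),
        }
    )
    return table


# ---------------------------------------------------------------------------
# fixture set
# ---------------------------------------------------------------------------


def sample_sheet(panel: PanelConfig) -> pd.DataFrame:
    """Sample sheet TSV layout: id, pool, subgroup, inbred_penalty,
    replicate_of, parent1, parent2."""
    rows = []
    for s in panel.samples:
        p1, p2 = (s.parents if s.parents else ("", ""))
        rows.append((s.id, s.pool, s.subgroup, s.inbred_penalty,
                     s.replicate_of or "", p1, p2))
    return pd.DataFrame(
        rows,
        columns=["id", "pool", "subgroup", "inbred_penalty",
                 "replicate_of", "parent1", "parent2"],
    )


def write_fixture_set(
    directory,
    genome: GenomeModel,
    panel: PanelConfig,
    calls: VariantCallSet | None = None,
    intensities: pd.DataFrame | None = None,
    seed: int | None = None,
    settings: dict | None = None,
) -> dict:
    """Write the simulated objects as plain-text fixtures and a manifest.

    Emits VCF v4.2 (sequencing calls), TSV (intensities, sample sheet), BED
    (genes, 0-based half-open) and ``manifest.json``; everything round-trips
    through the module readers.
    """
    import json
    from pathlib import Path

    from . import vcfio

    if not panel.samples:
        raise ConfigurationError("cannot write fixtures for an empty panel")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": seed,
        "settings": settings or {},
        "files": {},
        "chrom_lengths": {k: int(v) for k, v in genome.chrom_lengths.items()},
    }

    sheet_path = directory / "samples.tsv"
    sample_sheet(panel).to_csv(sheet_path, sep="\t", index=False)
    manifest["files"]["sample_sheet"] = sheet_path.name

    bed_path = directory / "genes.bed"
    vcfio.write_genes_bed(genome.genes, bed_path)
    manifest["files"]["genes_bed"] = bed_path.name

    if calls is not None:
        vcf_path = directory / "calls.vcf"
        vcfio.write_vcf(calls, vcf_path)
        manifest["files"]["vcf"] = vcf_path.name

    if intensities is not None:
        int_path = directory / "intensities.tsv"
        intensities.to_csv(int_path, sep="\t", index=False)
        manifest["files"]["intensities"] = int_path.name

    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
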