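"""Shared in-memory containers and genotype codes.

Two genotype alphabets are used through the pipeline:

* sequencing space: ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING`` for caller
  output (VCF orientation, sites x samples);
* array space: ``AA``/``AB``/``BB``/``OO``/``MISSING`` for intensity-derived
  calls, where allele A is the reference allele of the probed variant and
  ``OO`` marks the low-intensity off-target cluster.

Panel-level genotype matrices are samples x variants; the VCF-like
:class:`VariantCallSet` stores sites x samples to match file layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

# sequencing-space genotype codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

# array-space genotype codes (AA == two reference alleles)
AA = 0
AB = 1
BB = 2
OO = 3

ARRAY_LABELS = ("AA", "AB", "BB", "OO")


@dataclass
class VariantCallSet:
    """Caller-style variant records with per-line genotypes and depths.

    ``sites`` carries one row per variant with columns: chrom, pos (1-based),
    ref, alt (comma-joined for multi-allelic sites), vtype ('SNP'|'indel'),
    qual, dp (site depth), cn (genomic copy number), mq0f (fraction of reads
    with mapping quality 0), samtools_call, gatk_call (caller-support flags).
    ``genotypes`` and ``depths`` are (n_sites, n_samples) arrays aligned with
    ``sites`` row order and ``samples``.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    depths: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        n = len(self.sites)
        if self.genotypes.shape != (n, len(self.samples)):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n} sites x {len(self.samples)} samples"
            )
        if self.depths.shape != self.genotypes.shape:
            raise ValidationError("depth matrix shape does not match genotypes")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, mask: np.ndarray) -> "VariantCallSet":
        """Row-subset by boolean mask or integer index, preserving order."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantCallSet(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx].copy(),
            depths=self.depths[idx].copy(),
            samples=list(self.samples),
        )

    def copy(self) -> "VariantCallSet":
        return VariantCallSet(
            self.sites.copy(), self.genotypes.copy(), self.depths.copy(), list(self.samples)
        )


@dataclass
class FilterReport:
    """Per-filter accounting: input = pass + fail for every step."""

    steps: list = field(default_factory=list)  # (name, n_in, n_pass, n_fail)
    first_fail: dict = field(default_factory=dict)  # variant row id -> filter name

    def record(self, name: str, n_in: int, n_pass: int) -> None:
        self.steps.append((name, int(n_in), int(n_pass), int(n_in - n_pass)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_in", "n_pass", "n_fail"])

    def extend(self, other: "FilterReport") -> None:
        self.steps.extend(other.steps)
        for key, val in other.first_fail.items():
            self.first_fail.setdefault(key, val)
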