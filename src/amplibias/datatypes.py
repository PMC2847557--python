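"""Core containers shared across the pipeline.

Probe-level intensities are held dense, indexed by (probe_set_id,
probe_position) with one column per array; summarized expression is a
probe-set x array matrix on the log2 scale.  Array metadata (tissue,
protocol, replicate) travels alongside both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Protocol label carrying the second amplification cycle (the one whose
#: planted shifts and strongest 3' gradient the analysis hunts for).
TWO_CYCLE = "two_cycle"

DEFAULT_PROTOCOLS = ("one_cycle", "two_cycle", "ivt_e")
DEFAULT_TISSUES = ("MS", "EZ")

ARRAY_META_COLUMNS = ("tissue", "protocol", "replicate")


class ConfigurationError(ValueError):
    """A simulation or run configuration violates one of its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic probe-level generative model.

    All location/scale parameters are on the log2 scale.  ``gradient`` maps
    each protocol to the log2-unit drop across the full probe-index span
    (positive values produce 3' bias, i.e. higher signal at 3' probes).
    Planted shifts act only under the two-cycle protocol: ``n_over`` genes
    get a shift drawn uniformly from [shift_low, shift_high], ``n_under``
    genes the negated draw.
    """

    n_probe_sets: int = 2000
    n_probes_per_set: int = 11
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    protocols: tuple[str, ...] = DEFAULT_PROTOCOLS
    n_replicates: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    affinity_sd: float = 0.5
    gradient: dict = field(
        default_factory=lambda: {"one_cycle": 0.2, "two_cycle": 0.8, "ivt_e": 0.3}
    )
    tissue_effect_sd: float = 1.0
    n_over: int = 20
    n_under: int = 20
    shift_low: float = 2.0
    shift_high: float = 6.0
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the violated invariant."""
        if self.n_probe_sets < 1:
            raise ConfigurationError("n_probe_sets must be a positive count")
        if self.n_probes_per_set < 1:
            raise ConfigurationError("n_probes_per_set must be a positive count")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be a positive count")
        if self.n_over < 0 or self.n_under < 0:
            raise ConfigurationError("n_over and n_under must be non-negative")
        if self.n_over + self.n_under > self.n_probe_sets:
            raise ConfigurationError("n_over + n_under must not exceed n_probe_sets")
        if not (0 < self.shift_low <= self.shift_high):
            raise ConfigurationError(
                "shift bounds must satisfy 0 < shift_low <= shift_high"
            )
        for name in ("noise_sd", "affinity_sd", "baseline_sd", "tissue_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        missing = [p for p in self.protocols if p not in self.gradient]
        if missing:
            raise ConfigurationError(
                f"gradient missing entries for protocols: {missing}"
            )
        if len(self.tissues) < 1 or len(self.protocols) < 1:
            raise ConfigurationError("tissues and protocols must be non-empty")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated dataset.

    ``shifts`` maps each planted gene to its signed log2 shift (positive for
    over-amplified, negative for under-amplified under two-cycle).
    """

    over_genes: frozenset
    under_genes: frozenset
    shifts: dict
    gradients: dict
    seed: int

    def __post_init__(self):
        if self.over_genes & self.under_genes:
            raise ConfigurationError("over_genes and under_genes must be disjoint")
        for g in self.over_genes:
            if self.shifts[g] <= 0:
                raise ConfigurationError(f"over gene {g} has non-positive shift")
        for g in self.under_genes:
            if self.shifts[g] >= 0:
                raise ConfigurationError(f"under gene {g} has non-negative shift")


@dataclass
class ProbeLevelDataset:
    """Dense probe-level intensities plus array metadata.

    ``intensities``: linear-scale values, rows MultiIndex
    (probe_set_id, probe_position), one column per array_id, all > 0.
    ``arrays``: DataFrame indexed by array_id with columns tissue, protocol,
    replicate.  Probe positions run 1 (5'-most) .. n (3'-most).
    """

    intensities: pd.DataFrame
    arrays: pd.DataFrame

    @property
    def n_probes_per_set(self) -> int:
        return int(self.intensities.groupby(level=0).size().iloc[0])

    def validate(self) -> None:
        if list(self.intensities.columns) != list(self.arrays.index):
            missing = set(self.intensities.columns) ^ set(self.arrays.index)
            raise ValueError(f"array columns and metadata disagree: {sorted(missing)}")
        if (self.intensities.to_numpy() <= 0).any():
            raise ValueError("probe intensities must all be positive")
        counts = self.intensities.groupby(level=0).size()
        if counts.nunique() != 1:
            ragged = counts[counts != counts.mode().iloc[0]]
            raise ValueError(
                f"ragged probe sets (positions missing): {list(ragged.index[:5])}"
            )


@dataclass
class ExpressionMatrix:
    """Summarized probe-set x array expression, log2 scale.

    Reported "expression level" on the natural scale means ``2**value``.
    """

    values: pd.DataFrame
    arrays: pd.DataFrame

    def validate(self) -> None:
        if list(self.values.columns) != list(self.arrays.index):
            missing = set(self.values.columns) ^ set(self.arrays.index)
            raise ValueError(f"array columns and metadata disagree: {sorted(missing)}")
        if not pd.api.types.is_float_dtype(self.values.to_numpy().dtype):
            raise ValueError("expression values must be float")
        import numpy as np

        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def natural_scale(self) -> pd.DataFrame:
        """Antilog: 2**log2-expression, the reporting convention."""
        return 2.0 ** self.values
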