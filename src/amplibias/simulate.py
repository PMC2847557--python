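"""Synthetic probe-level data with the structure the analysis assumes.

The generative model is additive on the log2 scale, per
(gene g, tissue t, protocol k, replicate r, probe p):

    y = theta_g + tau_{g,t} + phi_{g,p}
        + delta_k * (p - p_mid) / span
        + s_g * 1[k == two_cycle]
        + eps

with theta ~ N(baseline_mean, baseline_sd), tau ~ N(0, tissue_effect_sd),
phi ~ N(0, affinity_sd), p_mid = (1 + n_probes)/2, span = (n_probes - 1)/2,
s_g the planted signed shift (0 for non-planted genes) and eps i.i.d.
N(0, noise_sd) per cell.  Intensities are 2**y, floored at 1 so log2 stays
defined.  delta_k > 0 tilts signal toward 3' probes (p > p_mid), giving the
negative bias-statistic values expected of amplified material.

Everything is drawn from one ``numpy.random.default_rng(seed)`` stream in a
fixed order, so identical (config, seed) gives bit-identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    TWO_CYCLE,
    ProbeLevelDataset,
    SimConfig,
    SimTruth,
)

__all__ = ["generate_probe_data", "array_id"]


def array_id(tissue: str, protocol: str, replicate: int) -> str:
    return f"{tissue}_{protocol}_r{replicate}"


def _probe_set_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"PS{i:0{width}d}" for i in range(1, n + 1)]


def generate_probe_data(config: SimConfig) -> tuple[ProbeLevelDataset, SimTruth]:
    """Simulate a dense probe-level dataset and its ground truth.

    Returns the dataset (linear-scale intensities, array metadata) and a
    :class:`SimTruth` recording which genes were planted with which signed
    log2 shift, plus the per-protocol 3' gradient magnitudes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _probe_set_ids(config.n_probe_sets)
    n_g, n_p = config.n_probe_sets, config.n_probes_per_set
    tissues, protocols = list(config.tissues), list(config.protocols)
    reps = range(1, config.n_replicates + 1)

    theta = rng.normal(config.baseline_mean, config.baseline_sd, size=n_g)
    tau = rng.normal(0.0, config.tissue_effect_sd, size=(n_g, len(tissues)))
    phi = rng.normal(0.0, config.affinity_sd, size=(n_g, n_p))

    # Planted shifts: choose genes without replacement, magnitudes uniform
    # in [shift_low, shift_high], over genes positive / under negative.
    n_planted = config.n_over + config.n_under
    planted_idx = rng.choice(n_g, size=n_planted, replace=False)
    magnitudes = rng.uniform(config.shift_low, config.shift_high, size=n_planted)
    shifts = np.zeros(n_g)
    over_idx = planted_idx[: config.n_over]
    under_idx = planted_idx[config.n_over :]
    shifts[over_idx] = magnitudes[: config.n_over]
    shifts[under_idx] = -magnitudes[config.n_over :]

    positions = np.arange(1, n_p + 1, dtype=float)
    p_mid = (1 + n_p) / 2.0
    span = (n_p - 1) / 2.0 if n_p > 1 else 1.0
    rel_pos = (positions - p_mid) / span  # in [-1, 1]

    meta_rows = []
    columns = {}
    for t_i, tissue in enumerate(tissues):
        for protocol in protocols:
            delta = float(config.gradient[protocol])
            for rep in reps:
                aid = array_id(tissue, protocol, rep)
                meta_rows.append((aid, tissue, protocol, rep))
                y = (
                    theta[:, None]
                    + tau[:, t_i][:, None]
                    + phi
                    + delta * rel_pos[None, :]
                )
                if protocol == TWO_CYCLE:
                    y = y + shifts[:, None]
                if config.noise_sd > 0:
                    y = y + rng.normal(0.0, config.noise_sd, size=(n_g, n_p))
                columns[aid] = np.maximum(2.0 ** y, 1.0).ravel()

    index = pd.MultiIndex.from_product(
        [genes, np.arange(1, n_p + 1)], names=["probe_set_id", "probe_position"]
    )
    intensities = pd.DataFrame(columns, index=index)
    arrays = pd.DataFrame(
        [(t, p, r) for _, t, p, r in meta_rows],
        index=pd.Index([a for a, *_ in meta_rows], name="array_id"),
        columns=["tissue", "protocol", "replicate"],
    )

    truth = SimTruth(
        over_genes=frozenset(genes[i] for i in over_idx),
        under_genes=frozenset(genes[i] for i in under_idx),
        shifts={genes[i]: float(shifts[i]) for i in planted_idx},
        gradients={p: float(config.gradient[p]) for p in protocols},
        seed=config.seed,
    )
    dataset = ProbeLevelDataset(intensities=intensities, arrays=arrays)
    return dataset, truth
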