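"""Synthetic data generators with attached ground truth.

The study's raw measurements (immunoblot chase densitometry, confocal
colocalization counts, flow-cytometry apoptosis percentages) are not
deposited, so every fitting stage is exercised against synthetic data whose
generating parameters are known.  Each generator is deterministic given its
seed and returns the ground truth alongside the data so downstream recovery
tests always have an oracle.

Emulated assays:

* cycloheximide-chase style Bik decay curves per cell line / treatment,
* per-cell mitochondrial colocalization fractions (truncated normal around
  45% +/- 13%, 30 cells),
* endpoint apoptosis percentages per treatment arm with binomial counting
  noise (300 cells scored per arm by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bik import BikParams, DecayTimecourse, apply_herbimycin, decay_curve
from .network import ApoptosisParams, CellLineSpec, PARENTAL_CELL, SRC_CELL
from .treatments import TreatmentSpec, simulate_treated

__all__ = [
    "NoiseModel",
    "DEFAULT_CHASE_TIMES",
    "gen_bik_decay",
    "gen_colocalization",
    "gen_apoptosis_endpoints",
]

#: Plausible chase sampling design: 0-6 h at 30-min resolution.
DEFAULT_CHASE_TIMES = tuple(float(t) for t in range(0, 361, 30))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the generators.

    kinds: ``multiplicative-lognormal`` (scale = CV), ``additive-gaussian``
    (scale = SD), ``binomial-count`` (scale = cells scored), ``none``.
    """

    kind: str = "multiplicative-lognormal"
    scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative-lognormal", "additive-gaussian",
                             "binomial-count", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.scale == 0:
            return values.copy()
        if self.kind == "multiplicative-lognormal":
            sigma = np.sqrt(np.log1p(self.scale**2))  # CV -> lognormal sigma
            return values * rng.lognormal(-0.5 * sigma**2, sigma, size=values.shape)
        if self.kind == "additive-gaussian":
            return values + rng.normal(0.0, self.scale, size=values.shape)
        # binomial-count: values are percentages, scale is the count depth
        depth = int(self.scale)
        return 100.0 * rng.binomial(depth, np.clip(values / 100.0, 0, 1)) / depth


def gen_bik_decay(
    params: BikParams,
    cell_line: str,
    times=DEFAULT_CHASE_TIMES,
    noise: NoiseModel = NoiseModel(kind="none"),
    herbimycin: bool = False,
) -> DecayTimecourse:
    """Chase-style relative Bik decay curve for one cell line.

    Simulates degradation with synthesis off from the pre-chase steady
    state, normalizes to t=0, applies noise, and clips into the valid
    relative range.  Herbimycin (98% Src inhibition, re-equilibrated before
    the chase) restores near-parental slow decay in transformed cells.
    """
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    p = apply_herbimycin(params, 0.98) if herbimycin else params
    clean = decay_curve(p, np.asarray(times, dtype=float))
    noisy = np.clip(noise.apply(clean, noise.rng()), 0.0, 1.5)
    return DecayTimecourse(
        times=tuple(float(t) for t in times),
        values=tuple(float(v) for v in noisy),
        cell_line=cell_line,
        treatment="herbimycin" if herbimycin else "none",
        ground_truth=params,
    )


def gen_colocalization(
    n_cells: int = 30,
    mean: float = 0.45,
    sd: float = 0.13,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell mitochondrial Bik fractions at 2 h of stimulus.

    Truncated-to-[0, 1] normal draws emulating image-analysis colocalization
    of Bik fluorescence with a mitochondrial marker in single cells.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full(n_cells, mean)
    out = np.empty(n_cells)
    filled = 0
    while filled < n_cells:  # rejection sampling preserves the normal shape
        draw = rng.normal(mean, sd, size=2 * (n_cells - filled))
        keep = draw[(draw >= 0.0) & (draw <= 1.0)][: n_cells - filled]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def gen_apoptosis_endpoints(
    params: ApoptosisParams,
    arms: dict[str, TreatmentSpec] | None = None,
    cells: tuple[CellLineSpec, ...] = (PARENTAL_CELL, SRC_CELL),
    noise: NoiseModel = NoiseModel(kind="binomial-count", scale=300),
    t_end: float = 480.0,
) -> list[dict]:
    """Endpoint apoptosis percentages per (cell line, arm).

    Simulates each arm with the supplied network parameters, then applies
    binomial counting noise (default 300 cells scored per arm, ~ +/-2.5
    points at 80%).  Each record carries the noise-free ground truth, so
    calibration round-trips have an exact target.
    """
    if arms is None:
        from .treatments import SCENARIOS
        arms = {k: SCENARIOS[k] for k in ("sts", "sts_herbimycin")}
    rng = noise.rng()
    records = []
    for cell in cells:
        for name, rx in arms.items():
            res = simulate_treated(cell, rx, net=params, t_end=t_end)
            true_pct = res.apoptotic_pct
            observed = float(noise.apply(np.array([true_pct]), rng)[0])
            records.append({
                "cell_line": cell.label,
                "arm": name,
                "treatment": rx,
                "observed_pct": observed,
                "true_pct": true_pct,
            })
    return records
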