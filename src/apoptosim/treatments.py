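"""Declarative drug/perturbation layer.

A treatment is applied as a pre-incubation: it modifies parameters and
total concentrations, then the system is re-equilibrated so that the
staurosporine stimulus (if any) starts from the perturbed steady state.
Identical treatment values are always applied to both cell lines,
mimicking systemic drug exposure.

Knobs and their biological surrogates:

* ``src_inhibition`` - herbimycin-like Src kinase inhibitor: removes a
  fraction of the Src-dependent Bik-ubiquitylation v_max, which raises the
  Bik steady state back toward the parental level.
* ``bcl2_depletion`` - ABT-737-like BH3 mimetic: removes nM from the
  anti-apoptotic pool and dissociates pro/anti-apoptotic complexes that no
  longer fit in the reduced pool.
* ``bax_delta`` - Bax downregulator (e.g. siRNA): removes nM of total Bax.
* ``bcl2_delta_generic`` - signed generic up/down-regulation of the pool.
* ``tbid_up`` - tBid upregulator acting through enhanced Bid transcription:
  raises total Bid by the given nM, so the stimulus has more substrate to
  truncate.  An alternative mode (``tbid_mode="tbid0"``) instead adds
  pre-formed tBid trapped by the pool at t=0; note that within a fixed Bid
  total that conversion removes truncatable Bid and is net protective, which
  is why it is not the default.
* ``staurosporine`` - the cytotoxic backbone; switches Bik activation and
  Bid truncation on at t=0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .bik import BikParams, apply_herbimycin, bik_steady_state, PARENTAL_BIK, SRC_BIK
from .network import (
    ApoptosisParams,
    CellLineSpec,
    NetworkState,
    build_initial_state,
    simulate,
)

__all__ = ["TreatmentSpec", "apply_treatment", "abt_alone_scan", "simulate_treated",
           "SCENARIOS", "bik_params_for"]


@dataclass(frozen=True)
class TreatmentSpec:
    staurosporine: bool = False
    src_inhibition: float = 0.0
    bcl2_depletion: float = 0.0
    bax_delta: float = 0.0
    bcl2_delta_generic: float = 0.0
    tbid_up: float = 0.0
    tbid_mode: str = "bid_total"  # or "tbid0"
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.src_inhibition <= 1.0:
            raise ValueError("src_inhibition must lie in [0, 1]")
        for name in ("bcl2_depletion", "bax_delta", "tbid_up"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tbid_mode not in ("bid_total", "tbid0"):
            raise ValueError(f"unknown tbid_mode {self.tbid_mode!r}")

    def describe(self) -> str:
        if self.label:
            return self.label
        parts = ["STS"] if self.staurosporine else []
        if self.src_inhibition:
            parts.append(f"src-inh {self.src_inhibition:.2f}")
        if self.bcl2_depletion:
            parts.append(f"bcl2 -{self.bcl2_depletion:g} nM")
        if self.bcl2_delta_generic:
            parts.append(f"bcl2 {self.bcl2_delta_generic:+g} nM")
        if self.bax_delta:
            parts.append(f"bax -{self.bax_delta:g} nM")
        if self.tbid_up:
            parts.append(f"tbid +{self.tbid_up:g} nM")
        return " + ".join(parts) if parts else "none"


def bik_params_for(cell: CellLineSpec) -> BikParams:
    """Default turnover parameters for a known cell line."""
    return PARENTAL_BIK if cell.label == "parental" else SRC_BIK


def apply_treatment(
    cell: CellLineSpec,
    rx: TreatmentSpec,
    bik: BikParams | None = None,
    net: ApoptosisParams | None = None,
) -> tuple[CellLineSpec, BikParams, ApoptosisParams, NetworkState]:
    """Pre-incubation: perturb totals/parameters and re-equilibrate.

    Returns the modified cell spec, Bik parameters, network parameters and
    the re-equilibrated initial state from which the (optional)
    staurosporine phase starts.

    Re-equilibration rules, in order:

    1. Src inhibition rescales the Bik v_max, and the Bik steady state is
       recomputed from the turnover model (the pre-incubation is long
       relative to the slowest Bik time constant).
    2. Bcl2 depletion (plus any generic delta) shrinks the pool; the pool
       first re-traps tBid0, and any remainder of tBid0 starts free
       (BH3-mimetic dissociation of anti/pro-apoptotic complexes).
    3. bax_delta shrinks total Bax (floored just above 0 to keep the spec
       well-formed).
    4. tbid_up raises total Bid (default mode) or pre-forms tBid within the
       existing pool (``tbid_mode="tbid0"``, capped at total Bid).
    """
    bik = bik if bik is not None else bik_params_for(cell)
    if net is None:
        from .network import DEFAULT_NETWORK_PARAMS
        net = DEFAULT_NETWORK_PARAMS

    new_bik = apply_herbimycin(bik, rx.src_inhibition) if rx.src_inhibition else bik
    bik_ss = bik_steady_state(new_bik).bik if rx.src_inhibition else cell.bik_ss

    bcl2_total = max(cell.bcl2_total - rx.bcl2_depletion + rx.bcl2_delta_generic, 1e-9)
    bax_total = max(cell.bax_total - rx.bax_delta, 1e-9)
    if rx.tbid_mode == "bid_total":
        bid_total = cell.bid_total + rx.tbid_up
        tbid0 = cell.tbid0
    else:  # pre-formed tBid within the existing Bid pool
        bid_total = cell.bid_total
        tbid0 = min(cell.tbid0 + rx.tbid_up, cell.bid_total)

    new_cell = replace(cell, bik_ss=bik_ss, bcl2_total=bcl2_total,
                       bax_total=bax_total, bid_total=bid_total, tbid0=tbid0)

    # initial complexation: the pool traps what it can of tbid0, the rest
    # starts free (relevant when the depleted pool is smaller than tbid0)
    trapped = min(tbid0, bcl2_total)
    free_tbid = tbid0 - trapped
    state = build_initial_state(replace(new_cell, tbid0=trapped))
    if free_tbid > 0:
        y = state.concentrations.copy()
        from .network import _IDX
        y[_IDX["tbid"]] += free_tbid
        y[_IDX["bid"]] -= free_tbid
        state = NetworkState(concentrations=y, n=100.0)
    return new_cell, new_bik, net, state


def simulate_treated(
    cell: CellLineSpec,
    rx: TreatmentSpec,
    net: ApoptosisParams | None = None,
    bik: BikParams | None = None,
    t_end: float = 480.0,
    **kw,
):
    """Apply a treatment and run the staurosporine phase (or mock)."""
    new_cell, _bik, net, state = apply_treatment(cell, rx, bik=bik, net=net)
    return simulate(new_cell, net, staurosporine=rx.staurosporine,
                    t_end=t_end, initial=state, **kw)


def abt_alone_scan(
    cell: CellLineSpec,
    net: ApoptosisParams | None = None,
    depletions=(0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0),
    t_end: float = 480.0,
) -> list[tuple[float, float]]:
    """Apoptotic % per Bcl2-pool depletion, without staurosporine.

    The model system is not "primed for death": absent the stimulus the
    ~1 nM of pre-existing tBid cannot drive Bax oligomerization even when
    the whole anti-apoptotic pool is neutralized, so every entry should be
    far below 1%.
    """
    out = []
    for d in depletions:
        rx = TreatmentSpec(staurosporine=False, bcl2_depletion=float(d))
        res = simulate_treated(cell, rx, net=net, t_end=t_end)
        out.append((float(d), res.apoptotic_pct))
    return out


#: The six in-silico arms used throughout the analyses.
SCENARIOS: dict[str, TreatmentSpec] = {
    "none": TreatmentSpec(label="none"),
    "sts": TreatmentSpec(staurosporine=True, label="STS"),
    "sts_herbimycin": TreatmentSpec(staurosporine=True, src_inhibition=0.98,
                                    label="STS + herbimycin"),
    "sts_abt737": TreatmentSpec(staurosporine=True, bcl2_depletion=182.0,
                                label="STS + ABT-737 (182 nM)"),
    "sts_bax_down": TreatmentSpec(staurosporine=True, bax_delta=36.0,
                                  label="STS + Bax downregulation"),
    "optimal_4_agent": TreatmentSpec(staurosporine=True, src_inhibition=0.98,
                                     bcl2_depletion=300.0, bax_delta=42.0,
                                     tbid_up=30.0, label="optimal 4-agent"),
}
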