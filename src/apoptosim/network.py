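"""The mitochondrial-apoptosis reaction network and cell-survival law.

Eleven molecular species (nM) cover the Bcl-2 family members that drive
staurosporine-induced apoptosis in NIH-3T3 fibroblasts: Bik (ER-resident
inactive form, mitochondrial active form, and Bcl2-bound complex), Bid and
its truncated activator form tBid (free and Bcl2-bound), Bax in closed,
open-membrane and oligomerized conformations plus its Bcl2-bound complex,
and a lumped anti-apoptotic pool ("Bcl2" = Bcl-2 + Bcl-xL + Mcl-1).

Reactions (mass action unless noted):

  R1   Bik_er            -> Bik_act              k_act (stimulus-gated)
  R2   Bik_act + Bcl2    -> C_bik                k_bik_bcl2
  R3   Bid               -> tBid                 k_trunc (stimulus-gated)
  R4   tBid + Bcl2       -> C_tbid               k_tbid_bcl2
  R5   C_tbid + Bik_act  -> C_bik + tBid         k_disp (sensitizer displacement)
  R6   Bax_c             -> Bax_o                kcat_bax*tBid*Bax_c/(km_bax+Bax_c)
                                                 ("kiss and run" catalysis by tBid)
  R7   2 Bax_o           -> 2 Bax_oligo          flux 2*k_dim*Bax_o^2
  R8   Bax_o + Bax_oligo -> 2 Bax_oligo          k_auto (autocatalytic, dominant)
  R9   Bax_o + Bcl2      -> C_bax                k_bax_bcl2
  R10  Bax_o             -> Bax_c                k_back

Complexes do not dissociate (except R5 displacement and drug-induced
dissociation handled by the treatment layer), so four linear conservation
laws hold: total Bik, total Bid, total Bax and total Bcl2 pool.
Bax_oligo is tracked in monomer equivalents to keep Bax conservation linear.

Cell death is a population-level threshold law on oligomerized Bax:

  dn/dt = -a * n * Bax_oligo^gamma / (Bax_oligo^gamma + bax_star^gamma)

where n is the percentage of surviving cells and bax_star the minimal
oligomerized-Bax concentration that triggers cytochrome-c release.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "ApoptosisParams",
    "CellLineSpec",
    "NetworkState",
    "SimulationResult",
    "network_rhs",
    "survival_rhs",
    "build_initial_state",
    "simulate",
    "estimate_kact",
    "threshold_fraction",
    "PARENTAL_CELL",
    "SRC_CELL",
    "SEED_NETWORK_PARAMS",
    "DEFAULT_NETWORK_PARAMS",
]

#: Species order used throughout (state vectors, trajectories, CSV output).
SPECIES = (
    "bik_er", "bik_act", "c_bik",
    "bid", "tbid", "c_tbid",
    "bax_c", "bax_o", "bax_oligo",
    "bcl2", "c_bax",
)
_IDX = {s: i for i, s in enumerate(SPECIES)}


@dataclass(frozen=True)
class ApoptosisParams:
    """Rate constants of the apoptosis network plus the death law.

    Units: first-order rates 1/min, association rates 1/(nM*min),
    kcat_bax 1/min with km_bax in nM, bax_star in nM, gamma dimensionless.
    """

    k_act: float = 0.005          # Bik ER->mitochondria activation
    k_bik_bcl2: float = 0.000105  # Bik_act + Bcl2 association (anchored)
    k_trunc: float = 0.00014      # Bid truncation into tBid
    k_tbid_bcl2: float = 0.000087  # tBid + Bcl2 association (anchored)
    k_disp: float = 0.88          # tBid displacement from Bcl2:tBid by Bik_act
    kcat_bax: float = 0.0104      # Bax activation by tBid (catalytic)
    km_bax: float = 114.0         # Michaelis constant of Bax activation
    k_dim: float = 0.000185       # dimeric nucleation of Bax oligomers
    k_auto: float = 0.0144        # autocatalytic oligomer growth
    k_bax_bcl2: float = 0.000021  # Bax_o + Bcl2 association
    k_back: float = 0.007         # Bax_o spontaneous closing
    gamma: float = 4.15           # death-law steepness
    death_rate: float = 0.0205    # maximal population death rate (1/min)
    bax_star: float = 13.0        # apoptotic threshold on Bax_oligo (nM)

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"ApoptosisParams.{name} must be finite and >= 0")

    def replace(self, **kw) -> "ApoptosisParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CellLineSpec:
    """Total Bcl-2 family concentrations (nM) for one cell line."""

    label: str
    bik_ss: float
    bax_total: float
    bcl2_total: float
    bid_total: float
    tbid0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("bik_ss", "bax_total", "bcl2_total", "bid_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CellLineSpec.{name} must be > 0")
        if not 0 <= self.tbid0 <= self.bid_total:
            raise ValueError("tbid0 must lie in [0, bid_total]")

    def replace(self, **kw) -> "CellLineSpec":
        return replace(self, **kw)


#: Parental NIH-3T3 fibroblasts (the "healthy" population).
PARENTAL_CELL = CellLineSpec("parental", bik_ss=50.0, bax_total=48.0,
                             bcl2_total=545.0, bid_total=52.0, tbid0=1.0)
#: v-Src-transformed fibroblasts (the "cancer" population).
SRC_CELL = CellLineSpec("src", bik_ss=9.2, bax_total=100.0,
                        bcl2_total=600.0, bid_total=40.0, tbid0=1.0)


@dataclass
class NetworkState:
    """Species concentrations (nM) plus surviving-cell percentage."""

    concentrations: np.ndarray  # length 11, SPECIES order
    n: float = 100.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (len(SPECIES),):
            raise ValueError(f"need {len(SPECIES)} concentrations in SPECIES order")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if not 0 <= self.n <= 100:
            raise ValueError("surviving percentage must lie in [0, 100]")

    def __getitem__(self, species: str) -> float:
        return float(self.concentrations[_IDX[species]])

    def conserved_totals(self) -> dict[str, float]:
        c = self
        return {
            "bik": c["bik_er"] + c["bik_act"] + c["c_bik"],
            "bid": c["bid"] + c["tbid"] + c["c_tbid"],
            "bax": c["bax_c"] + c["bax_o"] + c["bax_oligo"] + c["c_bax"],
            "bcl2": c["bcl2"] + c["c_bik"] + c["c_tbid"] + c["c_bax"],
        }


def network_rhs(y: np.ndarray, p: ApoptosisParams,
                k_act: float | None = None,
                k_trunc: float | None = None) -> np.ndarray:
    """Derivatives (nM/min) of the 11 species.

    ``k_act``/``k_trunc`` override the stimulus-gated rates (0 = no
    staurosporine); by default the parameter-set values are used.
    """
    if np.any(np.asarray(y) < 0):
        raise ValueError("negative concentration passed to network_rhs")
    ka = p.k_act if k_act is None else k_act
    kt = p.k_trunc if k_trunc is None else k_trunc
    return _rhs(y, p, ka, kt)


def _rhs(y, p, ka, kt):
    bik_er, bik_act, c_bik, bid, tbid, c_tbid, bax_c, bax_o, bax_oligo, bcl2, c_bax = y
    r1 = ka * bik_er
    r2 = p.k_bik_bcl2 * bik_act * bcl2
    r3 = kt * bid
    r4 = p.k_tbid_bcl2 * tbid * bcl2
    r5 = p.k_disp * c_tbid * bik_act
    r6 = p.kcat_bax * tbid * bax_c / (p.km_bax + bax_c)
    r7 = 2.0 * p.k_dim * bax_o * bax_o
    r8 = p.k_auto * bax_o * bax_oligo
    r9 = p.k_bax_bcl2 * bax_o * bcl2
    r10 = p.k_back * bax_o
    return np.array([
        -r1,                    # bik_er
        r1 - r2 - r5,           # bik_act
        r2 + r5,                # c_bik
        -r3,                    # bid
        r3 - r4 + r5,           # tbid
        r4 - r5,                # c_tbid
        -r6 + r10,              # bax_c
        r6 - r7 - r8 - r9 - r10,  # bax_o
        r7 + r8,                # bax_oligo
        -r2 - r4 - r9,          # bcl2
        r9,                     # c_bax
    ])


def survival_rhs(n: float, bax_oligo: float, p: ApoptosisParams) -> float:
    """dn/dt of the surviving-cell percentage (always <= 0).

    Hill-type gate on oligomerized Bax: negligible below bax_star, saturating
    at the maximal death rate ``a`` so the death rate cannot diverge.
    """
    if not 0 <= n <= 100 + 1e-9:
        raise ValueError("n must lie in [0, 100]")
    if bax_oligo < 0:
        raise ValueError("bax_oligo must be >= 0")
    return _survival_rate(n, bax_oligo, p)


def _survival_rate(n: float, bax_oligo: float, p: ApoptosisParams) -> float:
    # ratio form, guarded in log space: (bax_star/oligo)^gamma overflows for
    # tiny oligo at large gamma, where the death rate is simply zero
    if bax_oligo <= 0:
        return 0.0
    if p.bax_star > 0:
        log_r = p.gamma * math.log(p.bax_star / bax_oligo)
        if log_r > 500.0:
            return 0.0
        r = math.exp(log_r)
    else:
        r = 0.0
    return -p.death_rate * n / (1.0 + r)


def build_initial_state(cell: CellLineSpec) -> NetworkState:
    """Pre-stimulus steady state of a resting cell.

    Bik is entirely ER-resident at its turnover steady state; all Bax is in
    the closed conformation; all pre-existing tBid is trapped by the
    anti-apoptotic pool; no Bcl2:Bax_o complexes exist.  With the
    stimulus-gated rates at zero every reaction flux vanishes, so this is an
    exact fixed point of the network.
    """
    if cell.tbid0 > cell.bcl2_total:
        raise ValueError("tbid0 exceeds the Bcl2 pool: cannot trap all tBid")
    y = np.zeros(len(SPECIES))
    y[_IDX["bik_er"]] = cell.bik_ss
    y[_IDX["bax_c"]] = cell.bax_total
    y[_IDX["c_tbid"]] = cell.tbid0
    y[_IDX["bid"]] = cell.bid_total - cell.tbid0
    y[_IDX["bcl2"]] = cell.bcl2_total - cell.tbid0
    return NetworkState(concentrations=y, n=100.0)


@dataclass
class SimulationResult:
    """Dense trajectory of one in-silico experiment."""

    times: np.ndarray                 # min
    states: np.ndarray                # (n_times, 11) SPECIES order
    n: np.ndarray                     # surviving %, same grid
    cell_line: str
    treatment_label: str = ""
    threshold_crossing_min: float | None = None  # first t with Bax_oligo >= bax_star

    @property
    def apoptotic_pct(self) -> float:
        return float(100.0 - self.n[-1])

    @property
    def conservation_drift(self) -> float:
        totals = np.stack([
            self.states[:, [_IDX["bik_er"], _IDX["bik_act"], _IDX["c_bik"]]].sum(1),
            self.states[:, [_IDX["bid"], _IDX["tbid"], _IDX["c_tbid"]]].sum(1),
            self.states[:, [_IDX["bax_c"], _IDX["bax_o"], _IDX["bax_oligo"], _IDX["c_bax"]]].sum(1),
            self.states[:, [_IDX["bcl2"], _IDX["c_bik"], _IDX["c_tbid"], _IDX["c_bax"]]].sum(1),
        ])
        ref = totals[:, :1]
        with np.errstate(divide="ignore", invalid="ignore"):
            drift = np.abs(totals - ref) / np.where(ref > 0, ref, 1.0)
        return float(drift.max())

    def species(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]


def simulate(
    cell: CellLineSpec,
    params: ApoptosisParams,
    staurosporine: bool = True,
    t_end: float = 480.0,
    initial: NetworkState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    grid_min: float = 1.0,
) -> SimulationResult:
    """Integrate network + survival dynamics for ``t_end`` minutes.

    Staurosporine (2 uM, binary trigger) switches the Bik-activation and
    Bid-truncation rates on at t=0; without it both are zero and the initial
    state is a fixed point.  Uses LSODA with tight tolerances; dense output
    on a 1-min grid.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    state0 = initial if initial is not None else build_initial_state(cell)
    ka = params.k_act if staurosporine else 0.0
    kt = params.k_trunc if staurosporine else 0.0
    y0 = np.append(state0.concentrations, state0.n)

    def rhs(_t, y):
        dy = _rhs(np.maximum(y[:-1], 0.0), params, ka, kt)
        dn = _survival_rate(max(y[-1], 0.0), max(y[_IDX["bax_oligo"]], 0.0), params)
        return np.append(dy, dn)

    t_eval = np.arange(0.0, t_end + 0.5 * grid_min, grid_min)
    if t_eval[-1] > t_end:
        t_eval[-1] = t_end
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"network integration failed: {sol.message}")
    states = sol.y[:-1].T
    n = np.clip(sol.y[-1], 0.0, 100.0)
    oligo = states[:, _IDX["bax_oligo"]]
    above = np.nonzero(oligo >= params.bax_star)[0]
    crossing = float(sol.t[above[0]]) if above.size else None
    return SimulationResult(
        times=sol.t, states=states, n=n, cell_line=cell.label,
        treatment_label="staurosporine" if staurosporine else "none",
        threshold_crossing_min=crossing,
    )


def estimate_kact(mito_fraction: float, t: float) -> float:
    """First-order activation rate from a relocated fraction at time t.

    If ER->mitochondria relocation is first order with rate k, the
    mitochondrial fraction at time t is 1 - exp(-k*t); inverting gives
    k = -ln(1 - fraction)/t.  The observed 45% colocalization at 2 h yields
    k ~ 0.005/min.
    """
    if not 0 <= mito_fraction < 1:
        raise ValueError("mito_fraction must lie in [0, 1)")
    if t <= 0:
        raise ValueError("t must be > 0")
    return -math.log(1.0 - mito_fraction) / t


def threshold_fraction(mito_share: float, active_share: float) -> float:
    """Fraction of total Bax that is activated during apoptosis.

    Product of the share of Bax at mitochondria and the activated share of
    mitochondrial Bax (0.33 * 0.38 ~ 0.13); multiplied by a reference
    bax_total it gives the apoptotic threshold bax_star.
    """
    if not (0 <= mito_share <= 1 and 0 <= active_share <= 1):
        raise ValueError("shares must lie in [0, 1]")
    return mito_share * active_share


#: Seed values for calibration: literature-anchored association constants,
#: the relocation rate from the colocalization assay, and nominal guesses
#: for the remaining rates.  These seeds do NOT reproduce the endpoint
#: data with the reconstructed rate laws; the shipped defaults below are
#: the result of running `calibration.calibrate` on the documented problem.
SEED_NETWORK_PARAMS = ApoptosisParams()

#: Calibrated defaults (penalized least squares on the four endpoint
#: percentages under the trajectory constraint suite; see calibration
#: module).  Regenerate with analysis/03_calibrate_network.py.
DEFAULT_NETWORK_PARAMS = SEED_NETWORK_PARAMS  # placeholder, replaced below

def _load_default_params() -> ApoptosisParams:
    from importlib.resources import files
    import json

    path = files("apoptosim.data").joinpath("calibrated_network_params.json")
    with path.open() as fh:
        payload = json.load(fh)
    return ApoptosisParams(**payload["params"])


try:
    DEFAULT_NETWORK_PARAMS = _load_default_params()
except FileNotFoundError:  # pragma: no cover - only during bootstrap
    pass
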