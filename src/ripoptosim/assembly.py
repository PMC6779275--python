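"""Stochastic assembly of DISC/RIPoptosome platforms (reference engine).

Direct-method Gillespie simulation of the competitive, random assembly of
Casp8-activation platforms.  Each platform origin is tracked as a composition
vector (RIP1, RIP3, FADD, ProCasp8, cFLIPl/s, DED1-DED2 counts plus formed
dimers) together with a single terminal-site flag: binding of a DED-carrying
species (ProCasp8, cFLIP, free DED1-DED2) to the filament end blocks further
RIP1 recruitment until it dissociates.  Full filament sequence is not needed:
every observable (mass, per-origin counts, blocking) is a function of the
composition, and the small state space keeps brute-force master-equation
validation tractable.

Reaction channels per origin
----------------------------
RIP1 elongation (open end only) and dissociation; RIP3 recruitment to bound
RIP1 via RHIM (each recruitment increments the RIP1-RIP3 necrosome counter);
FADD binding to bound RIP1; ProCasp8 / cFLIPl / cFLIPs / free DED1-DED2
binding to FADD-exposed DED sites and to the filament end (blocking); reverse
dissociations; cis-dimerization of two platform-bound ProCasp8; hetero-
dimerization with bound cFLIP (catalytically dead by default); dimer
dissociation; dimer cleavage/activation releasing one active Casp8 dimer and
one free DED1-DED2.  Per receptor cluster: trans-dimerization of ProCasp8 on
two distinct origins (zero channels when clustering is disrupted).

This pure-Python engine is the specification of the reaction network; the
numba kernels in :mod:`ripoptosim._kernels` implement the same schedule for
large ensembles and are statistically cross-checked against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import KineticParameters, ModelConfig, ValidationError
from .receptors import ClusterAssignment, ClusterSizeDistribution, assign_clusters, total_trimer_count

__all__ = [
    "PlatformOrigin",
    "StochasticCellState",
    "ReactionChannel",
    "make_initial_state",
    "build_propensities",
    "apply_channel",
    "gillespie_step",
    "simulate_assembly",
    "platform_mass",
    "AssemblyTrajectory",
]

# terminal-site occupant codes
TERM_OPEN, TERM_P8, TERM_FL, TERM_FS, TERM_D12 = 0, 1, 2, 3, 4


@dataclass
class PlatformOrigin:
    """Composition of one DISC/RIPoptosome platform."""

    n_rip1: int = 1          # seeded with one RIP1
    n_rip3: int = 0
    n_fadd: int = 0
    n_procasp8: int = 0      # site-bound monomers
    n_cflip_l: int = 0
    n_cflip_s: int = 0
    n_ded12: int = 0
    n_dimer: int = 0         # formed ProCasp8 homodimers awaiting activation
    n_het_l: int = 0         # ProCasp8-cFLIPl heterodimers
    n_het_s: int = 0         # ProCasp8-cFLIPs heterodimers
    terminal: int = TERM_OPEN
    cluster_id: int = 0

    @property
    def occupied_sites(self) -> int:
        return (self.n_procasp8 + self.n_cflip_l + self.n_cflip_s + self.n_ded12
                + 2 * self.n_dimer + 2 * self.n_het_l + 2 * self.n_het_s)

    @property
    def free_ded_sites(self) -> int:
        return self.n_fadd - self.occupied_sites

    def copy(self) -> "PlatformOrigin":
        return PlatformOrigin(**self.__dict__)

    def key(self) -> tuple:
        return (self.n_rip1, self.n_rip3, self.n_fadd, self.n_procasp8,
                self.n_cflip_l, self.n_cflip_s, self.n_ded12, self.n_dimer,
                self.n_het_l, self.n_het_s, self.terminal)


@dataclass
class StochasticCellState:
    """Free cytosolic pools (counts), platforms and cumulative outputs."""

    config: ModelConfig
    rip1: int
    rip3: int
    fadd: int
    procasp8: int
    cflip_l: int
    cflip_s: int
    ded12: int
    platforms: list = field(default_factory=list)
    assignment: ClusterAssignment | None = None
    active_casp8_dimers: int = 0     # cumulative released dimers
    active_casp8_monomers: int = 0   # from active cFLIPl heterodimers, if enabled
    rip1_rip3_heterodimers: int = 0  # cumulative necrosome counter
    ded12_released: int = 0          # cumulative DED1-DED2 released on activation
    clock: float = 0.0

    @property
    def copies_per_nm(self) -> float:
        return self.config.copies_per_nm

    def pool_nm(self, name: str) -> float:
        return getattr(self, name) / self.copies_per_nm

    def copy(self) -> "StochasticCellState":
        new = StochasticCellState(
            config=self.config, rip1=self.rip1, rip3=self.rip3, fadd=self.fadd,
            procasp8=self.procasp8, cflip_l=self.cflip_l, cflip_s=self.cflip_s,
            ded12=self.ded12,
            platforms=[p.copy() for p in self.platforms],
            assignment=self.assignment,
            active_casp8_dimers=self.active_casp8_dimers,
            active_casp8_monomers=self.active_casp8_monomers,
            rip1_rip3_heterodimers=self.rip1_rip3_heterodimers,
            ded12_released=self.ded12_released,
            clock=self.clock,
        )
        return new

    def key(self) -> tuple:
        return ((self.rip1, self.rip3, self.fadd, self.procasp8, self.cflip_l,
                 self.cflip_s, self.ded12, self.active_casp8_dimers),
                tuple(p.key() for p in self.platforms))

    # ---- conservation ledgers -------------------------------------------
    def species_totals(self) -> dict:
        """Total molecule ledgers; constant over any reaction sequence."""
        t = {
            "rip1": self.rip1 + sum(p.n_rip1 for p in self.platforms),
            "rip3": self.rip3 + sum(p.n_rip3 for p in self.platforms),
            "fadd": self.fadd + sum(p.n_fadd for p in self.platforms),
            "procasp8": self.procasp8 + 2 * self.active_casp8_dimers
            + self.active_casp8_monomers
            + sum(p.n_procasp8 + 2 * p.n_dimer + p.n_het_l + p.n_het_s
                  + (1 if p.terminal == TERM_P8 else 0) for p in self.platforms),
            "cflip_l": self.cflip_l
            + sum(p.n_cflip_l + p.n_het_l + (1 if p.terminal == TERM_FL else 0)
                  for p in self.platforms),
            "cflip_s": self.cflip_s
            + sum(p.n_cflip_s + p.n_het_s + (1 if p.terminal == TERM_FS else 0)
                  for p in self.platforms),
            # DED1-DED2 is created on activation: subtract the cumulative
            # source so the ledger is constant
            "ded12": self.ded12
            + sum(p.n_ded12 + (1 if p.terminal == TERM_D12 else 0)
                  for p in self.platforms)
            - self.ded12_released,
        }
        return t


def make_initial_state(
    cfg: ModelConfig,
    dose_ng_ml: float,
    clustering: bool,
    rng: np.random.Generator,
    n_origins: int | None = None,
) -> StochasticCellState:
    """Build the t=0 cell state for a dose/clustering scenario.

    Each trimeric receptor-ligand complex spawns one platform origin seeded
    with a single RIP1 molecule, debited from the cytosolic RIP1 pool.
    """
    if n_origins is None:
        n_origins = total_trimer_count(cfg, dose_ng_ml)
    dist = ClusterSizeDistribution.from_config(cfg)
    assignment = assign_clusters(n_origins, dist, clustering, rng)
    origin_cluster = assignment.origin_to_cluster() if n_origins else np.empty(0, int)

    scale = cfg.copies_per_nm
    init = cfg.initial_nm
    pools = {
        name: int(round(getattr(init, name) * scale))
        for name in ("rip1", "rip3", "fadd", "procasp8", "cflip_l", "cflip_s")
    }
    seeds = min(n_origins, pools["rip1"])
    if seeds < n_origins:
        raise ValidationError(
            f"RIP1 pool ({pools['rip1']}) cannot seed {n_origins} origins"
        )
    pools["rip1"] -= n_origins
    platforms = [
        PlatformOrigin(cluster_id=int(origin_cluster[i])) for i in range(n_origins)
    ]
    return StochasticCellState(
        config=cfg, ded12=0, platforms=platforms, assignment=assignment, **pools
    )


@dataclass(frozen=True)
class ReactionChannel:
    """One enabled reaction: kind, target origin(s) and propensity (min^-1)."""

    kind: str
    origin: int = -1          # index into state.platforms (-1: none)
    partner: int = -1         # second origin for trans channels
    propensity: float = 0.0


# (kind, pool attr, origin attr, terminal code)
_DED_SPECIES = (
    ("procasp8", "procasp8", "n_procasp8", TERM_P8),
    ("cflip_l", "cflip_l", "n_cflip_l", TERM_FL),
    ("cflip_s", "cflip_s", "n_cflip_s", TERM_FS),
    ("ded12", "ded12", "n_ded12", TERM_D12),
)

_TERM_TO_POOL = {TERM_P8: "procasp8", TERM_FL: "cflip_l",
                 TERM_FS: "cflip_s", TERM_D12: "ded12"}


def _kon(rates: KineticParameters, species: str) -> float:
    return getattr(rates, f"kon_{species}_ded")


def _koff(rates: KineticParameters, species: str) -> float:
    return getattr(rates, f"koff_{species}_ded")


def build_propensities(state: StochasticCellState, params: KineticParameters | None = None):
    """Enumerate every enabled reaction channel with its propensity.

    Bimolecular propensities are ``kon_nM * [free pool in nM] * (site count)``
    so that per-copy rates follow from the configured cell volume.  Trans
    channels are enumerated per unordered origin pair within a cluster and
    vanish when clustering is disrupted (singleton clusters).
    """
    rates = params if params is not None else state.config.rates
    scale = state.copies_per_nm
    r1_nm = state.rip1 / scale
    r3_nm = state.rip3 / scale
    f_nm = state.fadd / scale
    pool_nm = {name: getattr(state, name) / scale
               for name in ("procasp8", "cflip_l", "cflip_s", "ded12")}

    channels: list[ReactionChannel] = []
    add = channels.append
    for i, p in enumerate(state.platforms):
        if p.terminal == TERM_OPEN:
            if r1_nm > 0:
                add(ReactionChannel("rip1_elongation", i,
                                    propensity=rates.kon_rip1_rip1 * r1_nm))
            for kind, pool, _attr, _code in _DED_SPECIES:
                if pool_nm[pool] > 0:
                    a = _kon(rates, kind) * pool_nm[pool]
                    if a > 0:
                        add(ReactionChannel(f"terminal_block_{kind}", i, propensity=a))
        else:
            occ = _TERM_TO_POOL[p.terminal]
            a = _koff(rates, occ)
            if a > 0:
                add(ReactionChannel("terminal_unblock", i, propensity=a))
        if p.n_rip1 > 1 and rates.koff_rip1_rip1 > 0:
            add(ReactionChannel("rip1_dissociation", i,
                                propensity=rates.koff_rip1_rip1 * (p.n_rip1 - 1)))
        if r3_nm > 0 and p.n_rip1 > 0:
            a = rates.kon_rip3_rip1 * r3_nm * p.n_rip1
            if a > 0:
                add(ReactionChannel("rip3_binding", i, propensity=a))
        if p.n_rip3 > 0 and rates.koff_rip3_rip1 > 0:
            add(ReactionChannel("rip3_dissociation", i,
                                propensity=rates.koff_rip3_rip1 * p.n_rip3))
        if f_nm > 0:
            a = rates.kon_fadd_platform * f_nm  # per-platform recruitment
            if a > 0:
                add(ReactionChannel("fadd_binding", i, propensity=a))
        free_sites = p.free_ded_sites
        if free_sites > 0 and rates.koff_fadd_platform > 0:
            # only FADD whose DED site is unoccupied can leave
            add(ReactionChannel("fadd_dissociation", i,
                                propensity=rates.koff_fadd_platform * free_sites))
        if free_sites > 0:
            for kind, pool, _attr, _code in _DED_SPECIES:
                a = _kon(rates, kind) * pool_nm[pool] * free_sites
                if a > 0:
                    add(ReactionChannel(f"{kind}_binding", i, propensity=a))
        for kind, _pool, attr, _code in _DED_SPECIES:
            n = getattr(p, attr)
            if n > 0:
                a = _koff(rates, kind) * n
                if a > 0:
                    add(ReactionChannel(f"{kind}_dissociation", i, propensity=a))
        if p.n_procasp8 >= 2 and rates.k_cis_dimer > 0:
            add(ReactionChannel(
                "cis_dimerization", i,
                propensity=rates.k_cis_dimer * p.n_procasp8 * (p.n_procasp8 - 1) / 2.0))
        if p.n_procasp8 >= 1 and rates.k_cis_dimer > 0:
            if p.n_cflip_l > 0:
                add(ReactionChannel("het_l_formation", i,
                                    propensity=rates.k_cis_dimer * p.n_procasp8 * p.n_cflip_l))
            if p.n_cflip_s > 0:
                add(ReactionChannel("het_s_formation", i,
                                    propensity=rates.k_cis_dimer * p.n_procasp8 * p.n_cflip_s))
        if p.n_dimer > 0:
            if rates.k_dimer_diss > 0:
                add(ReactionChannel("dimer_dissociation", i,
                                    propensity=rates.k_dimer_diss * p.n_dimer))
            if rates.k_casp8_activation > 0:
                add(ReactionChannel("casp8_activation", i,
                                    propensity=rates.k_casp8_activation * p.n_dimer))
        if p.n_het_l > 0:
            if rates.k_dimer_diss > 0:
                add(ReactionChannel("het_l_dissociation", i,
                                    propensity=rates.k_dimer_diss * p.n_het_l))
            act = rates.k_casp8_activation * rates.cflipl_heterodimer_activity
            if act > 0:
                add(ReactionChannel("het_l_activation", i,
                                    propensity=act * p.n_het_l))
        if p.n_het_s > 0 and rates.k_dimer_diss > 0:
            add(ReactionChannel("het_s_dissociation", i,
                                propensity=rates.k_dimer_diss * p.n_het_s))

    # trans-dimerization: unordered origin pairs within each cluster
    if (state.assignment is not None and state.assignment.clustering_enabled
            and rates.k_trans_dimer > 0):
        for members in state.assignment.clusters:
            if len(members) < 2:
                continue
            for a_idx in range(len(members)):
                i = members[a_idx]
                ni = state.platforms[i].n_procasp8
                if ni == 0:
                    continue
                for b_idx in range(a_idx + 1, len(members)):
                    j = members[b_idx]
                    nj = state.platforms[j].n_procasp8
                    if nj == 0:
                        continue
                    add(ReactionChannel("trans_dimerization", i, j,
                                        propensity=rates.k_trans_dimer * ni * nj))
    return channels


def apply_channel(state: StochasticCellState, ch: ReactionChannel) -> None:
    """Apply one reaction's state update in place (atomic)."""
    p = state.platforms[ch.origin] if ch.origin >= 0 else None
    kind = ch.kind
    if kind == "rip1_elongation":
        state.rip1 -= 1
        p.n_rip1 += 1
    elif kind == "rip1_dissociation":
        p.n_rip1 -= 1
        state.rip1 += 1
    elif kind == "rip3_binding":
        state.rip3 -= 1
        p.n_rip3 += 1
        state.rip1_rip3_heterodimers += 1
    elif kind == "rip3_dissociation":
        p.n_rip3 -= 1
        state.rip3 += 1
    elif kind == "fadd_binding":
        state.fadd -= 1
        p.n_fadd += 1
    elif kind == "fadd_dissociation":
        p.n_fadd -= 1
        state.fadd += 1
    elif kind.endswith("_binding"):
        species = kind[: -len("_binding")]
        setattr(state, species, getattr(state, species) - 1)
        attr = dict((k, a) for k, _pl, a, _c in _DED_SPECIES)[species]
        setattr(p, attr, getattr(p, attr) + 1)
    elif kind.endswith("_dissociation") and kind.split("_dissociation")[0] in (
            "procasp8", "cflip_l", "cflip_s", "ded12"):
        species = kind[: -len("_dissociation")]
        attr = dict((k, a) for k, _pl, a, _c in _DED_SPECIES)[species]
        setattr(p, attr, getattr(p, attr) - 1)
        setattr(state, species, getattr(state, species) + 1)
    elif kind.startswith("terminal_block_"):
        species = kind[len("terminal_block_"):]
        code = dict((k, c) for k, _pl, _a, c in _DED_SPECIES)[species]
        setattr(state, species, getattr(state, species) - 1)
        p.terminal = code
    elif kind == "terminal_unblock":
        pool = _TERM_TO_POOL[p.terminal]
        setattr(state, pool, getattr(state, pool) + 1)
        p.terminal = TERM_OPEN
    elif kind == "cis_dimerization":
        p.n_procasp8 -= 2
        p.n_dimer += 1
    elif kind == "trans_dimerization":
        q = state.platforms[ch.partner]
        p.n_procasp8 -= 1
        q.n_procasp8 -= 1
        p.n_dimer += 1  # dimer hosted on the first origin of the pair
    elif kind == "dimer_dissociation":
        p.n_dimer -= 1
        p.n_procasp8 += 2
    elif kind == "casp8_activation":
        p.n_dimer -= 1
        state.active_casp8_dimers += 1
        state.ded12 += 1
        state.ded12_released += 1
    elif kind == "het_l_formation":
        p.n_procasp8 -= 1
        p.n_cflip_l -= 1
        p.n_het_l += 1
    elif kind == "het_s_formation":
        p.n_procasp8 -= 1
        p.n_cflip_s -= 1
        p.n_het_s += 1
    elif kind == "het_l_dissociation":
        p.n_het_l -= 1
        p.n_procasp8 += 1
        p.n_cflip_l += 1
    elif kind == "het_s_dissociation":
        p.n_het_s -= 1
        p.n_procasp8 += 1
        p.n_cflip_s += 1
    elif kind == "het_l_activation":
        p.n_het_l -= 1
        p.n_cflip_l += 1
        state.active_casp8_monomers += 1
        state.ded12 += 1
        state.ded12_released += 1
    else:  # pragma: no cover
        raise ValueError(f"unknown channel kind {kind!r}")


def gillespie_step(state: StochasticCellState, channels, rng: np.random.Generator):
    """One direct-method step: sample waiting time and fire one channel.

    Returns ``(state, dt)``; ``dt`` is ``inf`` (no event, state untouched)
    when the total propensity is zero.
    """
    if not channels:
        return state, math.inf
    props = np.fromiter((c.propensity for c in channels), dtype=float, count=len(channels))
    a0 = props.sum()
    if a0 <= 0:
        return state, math.inf
    dt = rng.exponential(1.0 / a0)
    pick = rng.random() * a0
    idx = int(np.searchsorted(np.cumsum(props), pick, side="right"))
    idx = min(idx, len(channels) - 1)
    apply_channel(state, channels[idx])
    state.clock += dt
    return state, dt


@dataclass
class AssemblyTrajectory:
    """Snapshots of an assembly-only simulation on a regular time grid."""

    times: np.ndarray
    active_casp8_dimers: np.ndarray
    ded12_released: np.ndarray
    rip1_rip3_heterodimers: np.ndarray
    mean_fadd_per_origin: np.ndarray
    max_platform_mass_kda: np.ndarray
    free_pools: dict
    compositions: list  # per grid time: list of PlatformOrigin copies (may be empty)


def platform_mass(origin: PlatformOrigin, masses) -> float:
    """Total platform mass in kDa (dimers count their two ProCasp8 subunits)."""
    m = (origin.n_rip1 * masses.rip1
         + origin.n_rip3 * masses.rip3
         + origin.n_fadd * masses.fadd
         + (origin.n_procasp8 + 2 * origin.n_dimer + origin.n_het_l
            + origin.n_het_s) * masses.procasp8
         + (origin.n_cflip_l + origin.n_het_l) * masses.cflip_l
         + (origin.n_cflip_s + origin.n_het_s) * masses.cflip_s
         + origin.n_ded12 * masses.ded12)
    if origin.terminal == TERM_P8:
        m += masses.procasp8
    elif origin.terminal == TERM_FL:
        m += masses.cflip_l
    elif origin.terminal == TERM_FS:
        m += masses.cflip_s
    elif origin.terminal == TERM_D12:
        m += masses.ded12
    return m


def simulate_assembly(
    init: StochasticCellState,
    t_end: float,
    record_grid: float,
    rng: np.random.Generator,
    keep_compositions: bool = False,
) -> AssemblyTrajectory:
    """Run the assembly SSA to ``t_end``, recording on a regular grid.

    Cumulative outputs (active Casp8 dimers, released DED1-DED2, RIP1-RIP3
    heterodimers) are monotone nondecreasing by construction.
    """
    if t_end <= 0:
        raise ValidationError(f"t_end must be > 0, got {t_end}")
    state = init
    masses = state.config.masses_kda
    times = np.arange(0.0, t_end + 0.5 * record_grid, record_grid)
    n = len(times)
    out = {
        "active": np.zeros(n), "ded12": np.zeros(n), "het": np.zeros(n),
        "fadd": np.zeros(n), "mass": np.zeros(n),
    }
    pools = {name: np.zeros(n) for name in
             ("rip1", "rip3", "fadd", "procasp8", "cflip_l", "cflip_s", "ded12")}
    comps: list = []

    def record(k):
        out["active"][k] = state.active_casp8_dimers
        out["ded12"][k] = state.ded12_released
        out["het"][k] = state.rip1_rip3_heterodimers
        n_org = len(state.platforms)
        out["fadd"][k] = (sum(p.n_fadd for p in state.platforms) / n_org
                          if n_org else 0.0)
        out["mass"][k] = (max(platform_mass(p, masses) for p in state.platforms)
                          if n_org else 0.0)
        for name in pools:
            pools[name][k] = getattr(state, name)
        if keep_compositions:
            comps.append([p.copy() for p in state.platforms])

    record(0)
    next_idx = 1
    while next_idx < n:
        channels = build_propensities(state)
        props = np.fromiter((c.propensity for c in channels), dtype=float,
                            count=len(channels))
        a0 = props.sum()
        if a0 <= 0:
            while next_idx < n:  # frozen state to the end of the grid
                record(next_idx)
                next_idx += 1
            break
        dt = rng.exponential(1.0 / a0)
        t_next = state.clock + dt
        # grid times passed by this waiting interval see the pre-event state
        while next_idx < n and times[next_idx] <= t_next:
            record(next_idx)
            next_idx += 1
        pick = rng.random() * a0
        idx = int(np.searchsorted(np.cumsum(props), pick, side="right"))
        apply_channel(state, channels[min(idx, len(channels) - 1)])
        state.clock = t_next
    return AssemblyTrajectory(
        times=times,
        active_casp8_dimers=out["active"],
        ded12_released=out["ded12"],
        rip1_rip3_heterodimers=out["het"],
        mean_fadd_per_origin=out["fadd"],
        max_platform_mass_kda=out["mass"],
        free_pools=pools,
        compositions=comps,
    )
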