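"""Rapid-equilibrium receptor engagement and cluster assignment.

Ligand binding to death receptors (TNFR1, DR4, DR5) is much faster than the
downstream platform assembly, so the number of ligand-bound receptors is taken
at its mass-action equilibrium

    [RL] = [R_total] / (Kd/[L] + 1)

The minimal signalling-competent unit is the trimeric receptor-ligand complex;
each trimer nucleates exactly one DISC/RIPoptosome platform origin, seeded
with a single RIP1 molecule.  Trimers are then distributed over membrane
clusters according to a calibrated cluster-size probability distribution; in
the disrupted-clustering scenario every origin sits in its own singleton
cluster and cross-origin (trans) Casp8 activation is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelConfig, ValidationError, ligand_dose_to_nm

__all__ = [
    "ClusterSizeDistribution",
    "ClusterAssignment",
    "bound_receptor_count",
    "trimer_count",
    "total_trimer_count",
    "assign_clusters",
]


@dataclass(frozen=True)
class ClusterSizeDistribution:
    """Probability mass over cluster sizes, in trimer units."""

    support: tuple
    probability: tuple

    def __post_init__(self):
        if len(self.support) != len(self.probability):
            raise ValidationError("support and probability differ in length")
        if len(self.support) == 0:
            raise ValidationError("cluster-size distribution is empty")
        if any(s < 1 or int(s) != s for s in self.support):
            raise ValidationError("cluster sizes must be integers >= 1")
        p = np.asarray(self.probability, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("probabilities must be >= 0 and sum to 1")

    @classmethod
    def from_config(cls, cfg: ModelConfig) -> "ClusterSizeDistribution":
        return cls(tuple(cfg.clustering.sizes), tuple(cfg.clustering.probabilities))

    @property
    def mean_size(self) -> float:
        return float(np.dot(self.support, self.probability))

    @property
    def pair_factor(self) -> float:
        """Expected ordered cross-pairs per origin: E[m(m-1)] / E[m].

        This is the size-biased mean number of *other* origins sharing a
        cluster with a randomly chosen origin; it scales the mean-field
        trans-dimerization rate.
        """
        s = np.asarray(self.support, dtype=float)
        p = np.asarray(self.probability, dtype=float)
        return float(np.dot(s * (s - 1.0), p) / np.dot(s, p))


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of platform origins into receptor clusters."""

    clusters: tuple  # tuple of tuples of origin indices
    clustering_enabled: bool = True

    @property
    def n_origins(self) -> int:
        return sum(len(c) for c in self.clusters)

    def origin_to_cluster(self) -> np.ndarray:
        out = np.empty(self.n_origins, dtype=np.int64)
        for ci, members in enumerate(self.clusters):
            for m in members:
                out[m] = ci
        return out


def bound_receptor_count(r_total: float, ligand_nm: float, kd_nm: float) -> float:
    """Equilibrium number of ligand-bound receptor monomers.

    Real-valued on purpose: discretisation happens once, at the trimer count,
    to avoid double rounding.
    """
    if kd_nm <= 0:
        raise ValidationError(f"Kd must be > 0, got {kd_nm}")
    if r_total < 0:
        raise ValidationError(f"receptor count must be >= 0, got {r_total}")
    if ligand_nm < 0:
        raise ValidationError(f"ligand concentration must be >= 0, got {ligand_nm}")
    if ligand_nm == 0:
        return 0.0
    return r_total / (kd_nm / ligand_nm + 1.0)


def trimer_count(rl: float) -> int:
    """Number of complete trimeric receptor-ligand complexes."""
    if rl < 0:
        raise ValidationError(f"bound receptor count must be >= 0, got {rl}")
    return int(rl // 3)


def total_trimer_count(cfg: ModelConfig, dose_ng_ml: float) -> int:
    """Pooled trimer count over all receptor species at the given ligand dose.

    Equilibrium binding is evaluated per species with its own Kd; the
    resulting trimers join one common origin pool (DISC and RIPoptosome
    origins are treated identically downstream).
    """
    ligand_nm = ligand_dose_to_nm(dose_ng_ml, cfg.simulation.ligand_mass_kda)
    total = 0
    for spec in cfg.receptors.values():
        total += trimer_count(bound_receptor_count(spec.count, ligand_nm, spec.kd_nm))
    return total


def assign_clusters(
    n_trimers: int,
    dist: ClusterSizeDistribution,
    clustering_enabled: bool,
    rng: np.random.Generator,
) -> ClusterAssignment:
    """Partition ``n_trimers`` platform origins into receptor clusters.

    Cluster sizes are drawn i.i.d. from ``dist`` until the trimer budget is
    exhausted; a residual that cannot fill the last sampled size forms one
    final smaller cluster.  Total origins across clusters always equals
    ``n_trimers`` exactly.  With clustering disrupted, every origin forms a
    singleton cluster.
    """
    if n_trimers < 0:
        raise ValidationError(f"trimer count must be >= 0, got {n_trimers}")
    if n_trimers == 0:
        return ClusterAssignment(clusters=(), clustering_enabled=clustering_enabled)
    if not clustering_enabled:
        return ClusterAssignment(
            clusters=tuple((i,) for i in range(n_trimers)),
            clustering_enabled=False,
        )
    sizes = []
    remaining = n_trimers
    support = np.asarray(dist.support, dtype=np.int64)
    prob = np.asarray(dist.probability, dtype=float)
    while remaining > 0:
        s = int(rng.choice(support, p=prob))
        if s > remaining:
            s = remaining  # residual forms one final undersized cluster
        sizes.append(s)
        remaining -= s
    clusters = []
    start = 0
    for s in sizes:
        clusters.append(tuple(range(start, start + s)))
        start += s
    return ClusterAssignment(clusters=tuple(clusters), clustering_enabled=True)
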