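"""Monod-Wyman-Changeux chemoreceptor cluster with methylation adaptation.

The cluster of Tar and Tsr homodimers (1:2 ratio) switches between *on*
and *off* as one unit. Its free-energy difference (in kT) sums a
methylation-dependent offset and a ligand-binding term per receptor:

    F = sum_type n_type * [ eps(m) + ln((1 + c/K_off) / (1 + c/K_on)) ]
    P_on = 1 / (1 + exp(F))

Attractant binding (K_off < K_on) raises F and so favors the *off*
state; methylation lowers the offset eps(m) = eps0 - eps1 * m and
favors *on*. Methylation integrates toward restoring the baseline
activity (CheR/CheB negative feedback), making the cluster a detector
of concentration *changes*: after any sustained step within the
methylation range, activity returns to baseline — larger steps need a
larger methylation shift and therefore adapt more slowly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class ReceptorCluster:
    n_tar: int = 6
    n_tsr: int = 12  # 1:2 Tar:Tsr
    # MeAsp dissociation constants, mM
    k_off_tar: float = 0.02
    k_on_tar: float = 0.5
    k_off_tsr: float = 100.0
    k_on_tsr: float = 1e6
    # offset free energy per receptor: eps(m) = eps0 - eps1 * m  (kT)
    eps0: float = 1.0
    eps1: float = 0.5
    methylation: float = 1.923  # baseline m for P_on ~ 1/3 at c = 0
    m_min: float = 0.0
    m_max: float = 8.0
    baseline_activity: float = 1.0 / 3.0
    adapt_rate: float = 0.15  # dm/dt per unit activity error, 1/s

    def __post_init__(self):
        if self.n_tsr != 2 * self.n_tar:
            raise ValueError("Tar:Tsr ratio must be 1:2")


def cluster_free_energy(cluster: ReceptorCluster, ligand: float) -> float:
    """Total free energy F (kT) at MeAsp concentration ``ligand`` (mM)."""
    eps = cluster.eps0 - cluster.eps1 * cluster.methylation
    f_tar = math.log(
        (1 + ligand / cluster.k_off_tar) / (1 + ligand / cluster.k_on_tar)
    )
    f_tsr = math.log(
        (1 + ligand / cluster.k_off_tsr) / (1 + ligand / cluster.k_on_tsr)
    )
    return cluster.n_tar * (eps + f_tar) + cluster.n_tsr * (eps + f_tsr)


def cluster_activity(cluster: ReceptorCluster, ligand: float) -> float:
    """P_on in [0, 1] for the current methylation level."""
    return 1.0 / (1.0 + math.exp(cluster_free_energy(cluster, ligand)))


def adapted_methylation(cluster: ReceptorCluster, ligand: float) -> float:
    """Methylation level at which activity equals baseline for ``ligand``.

    Useful for initializing a cluster already adapted to its ambient
    concentration (clipped to the valid methylation range).
    """
    p0 = cluster.baseline_activity
    f_target = math.log((1 - p0) / p0)  # total F at baseline activity
    f_tar = math.log(
        (1 + ligand / cluster.k_off_tar) / (1 + ligand / cluster.k_on_tar)
    )
    f_tsr = math.log(
        (1 + ligand / cluster.k_off_tsr) / (1 + ligand / cluster.k_on_tsr)
    )
    n = cluster.n_tar + cluster.n_tsr
    eps_star = (
        f_target - cluster.n_tar * f_tar - cluster.n_tsr * f_tsr
    ) / n
    m_star = (cluster.eps0 - eps_star) / cluster.eps1
    return min(max(m_star, cluster.m_min), cluster.m_max)


def receptor_update(
    cluster: ReceptorCluster, ligand: float, dt: float
) -> tuple[float, float]:
    """Advance methylation by ``dt`` and return (P_on, new methylation)."""
    if ligand < 0:
        raise ValueError("ligand concentration must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    activity = cluster_activity(cluster, ligand)
    dm = cluster.adapt_rate * (cluster.baseline_activity - activity) * dt
    cluster.methylation = min(
        max(cluster.methylation + dm, cluster.m_min), cluster.m_max
    )
    return cluster_activity(cluster, ligand), cluster.methylation
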