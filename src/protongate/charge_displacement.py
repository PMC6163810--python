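"""Slab charge profiles, center of charge, and its shift between states.

The gating charge measured electrophysiologically is the total charge
displacement across the membrane field, not the motion of any particular
side chain.  The surrogate computed here: partition the structure into slabs
along the membrane normal (default eleven 3 Å slices), sum the atomic
partial charges in each slab, and take the charge-weighted mean slab
midpoint as the center of charge.  The shift of that center between two
low-energy states, times the net charge and divided by the distance over
which the field drops, is an effective gating charge.

The center is defined on the signed net charge (the systems of interest
carry a net +2 e); a zero-net-charge input has no well-defined centroid and
is an error.  Both the slabwise center and the exact atomwise center
Σqz/Σq are available; displacement defaults to slabwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from protongate.structure_io import ChargedStructure

__all__ = [
    "SlabPartition",
    "ChargeProfile",
    "PartitionCoverageError",
    "UndefinedCenterError",
    "IncompatiblePartitionError",
    "slab_profile",
    "center_of_charge",
    "atomwise_center",
    "displacement",
    "effective_gating_charge",
]

CHARGE_TOL = 1e-6  # e; conservation bookkeeping tolerance


class PartitionCoverageError(ValueError):
    """An atom falls outside the slab partition (never silently truncated)."""


class UndefinedCenterError(ValueError):
    """Center of charge is undefined for zero total charge."""


class IncompatiblePartitionError(ValueError):
    """Two profiles built on different partitions cannot be compared."""


@dataclass(frozen=True)
class SlabPartition:
    """Half-open slabs [z0 + k·t, z0 + (k+1)·t) along the membrane normal."""

    thickness: float = 3.0
    n_slabs: int = 11
    z0: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if self.n_slabs < 1:
            raise ValueError(f"n_slabs must be >= 1, got {self.n_slabs}")

    @property
    def z_max(self) -> float:
        return self.z0 + self.n_slabs * self.thickness

    @property
    def midpoints(self) -> np.ndarray:
        return self.z0 + (np.arange(self.n_slabs) + 0.5) * self.thickness

    def slab_index(self, z: np.ndarray) -> np.ndarray:
        """Slab index per z; boundary atoms belong to the upper slab's lower edge."""
        return np.floor((np.asarray(z, dtype=float) - self.z0) / self.thickness).astype(int)

    @classmethod
    def for_structure(
        cls, s: ChargedStructure, thickness: float = 3.0, n_slabs: int | None = None
    ) -> "SlabPartition":
        """Partition anchored at the selection's minimum z, covering all atoms."""
        z = np.array([a.z for a in s.atoms])
        z0 = float(z.min())
        if n_slabs is None:
            span = float(z.max()) - z0
            n_slabs = max(1, int(np.floor(span / thickness)) + 1)
        return cls(thickness=thickness, n_slabs=n_slabs, z0=z0)


@dataclass(frozen=True)
class ChargeProfile:
    """Per-slab summed charges (e) on a given partition."""

    slab_charges: tuple[float, ...]
    partition: SlabPartition

    def __post_init__(self) -> None:
        if len(self.slab_charges) != self.partition.n_slabs:
            raise ValueError("slab_charges length does not match partition")

    @property
    def slab_midpoints(self) -> np.ndarray:
        return self.partition.midpoints

    @property
    def total_charge(self) -> float:
        return float(np.sum(self.slab_charges))

    @property
    def center_of_charge(self) -> float:
        return center_of_charge(self)


def slab_profile(s: ChargedStructure, p: SlabPartition | None = None) -> ChargeProfile:
    """Sum the atomic charges in each slab of ``p``.

    Charges must be attached.  Every atom must fall inside the partition;
    an out-of-range atom raises :class:`PartitionCoverageError` naming the
    offending z rather than being dropped, so charge is always conserved.
    """
    if p is None:
        p = SlabPartition.for_structure(s)
    z = np.array([a.z for a in s.atoms])
    q = s.charges
    idx = p.slab_index(z)
    bad = (idx < 0) | (idx >= p.n_slabs)
    if bad.any():
        z_bad = z[bad][0]
        raise PartitionCoverageError(
            f"atom at z={z_bad:.3f} Å outside partition [{p.z0}, {p.z_max}) Å"
        )
    sums = np.bincount(idx, weights=q, minlength=p.n_slabs)
    assert abs(sums.sum() - q.sum()) < CHARGE_TOL
    return ChargeProfile(slab_charges=tuple(float(x) for x in sums), partition=p)


def center_of_charge(prof: ChargeProfile) -> float:
    """Charge-weighted mean slab midpoint, Σ(Q_s·z_mid,s)/ΣQ_s, in Å."""
    total = prof.total_charge
    if abs(total) < CHARGE_TOL:
        raise UndefinedCenterError(
            "total charge is zero; signed-charge centroid undefined"
        )
    return float(np.dot(prof.slab_charges, prof.slab_midpoints) / total)


def atomwise_center(s: ChargedStructure) -> float:
    """Exact charge-weighted z centroid Σqz/Σq, in Å (no slab discretization)."""
    q = s.charges
    total = q.sum()
    if abs(total) < CHARGE_TOL:
        raise UndefinedCenterError(
            "total charge is zero; signed-charge centroid undefined"
        )
    z = np.array([a.z for a in s.atoms])
    return float(np.dot(q, z) / total)


def displacement(
    prof_a: ChargeProfile | float, prof_b: ChargeProfile | float
) -> float:
    """Center-of-charge shift of state A relative to state B, in Å.

    Positive means A's center lies further extracellular than B's.  Accepts
    two :class:`ChargeProfile` objects built on the same partition, or two
    already-computed centers (Å) directly.
    """
    if isinstance(prof_a, ChargeProfile) and isinstance(prof_b, ChargeProfile):
        if prof_a.partition != prof_b.partition:
            raise IncompatiblePartitionError(
                f"partitions differ: {prof_a.partition} vs {prof_b.partition}"
            )
        return center_of_charge(prof_a) - center_of_charge(prof_b)
    if isinstance(prof_a, ChargeProfile) or isinstance(prof_b, ChargeProfile):
        raise IncompatiblePartitionError(
            "mixed profile/center arguments; pass two profiles or two centers"
        )
    return float(prof_a) - float(prof_b)


def effective_gating_charge(
    delta: float, net_charge: float, field_drop_distance: float
) -> float:
    """Effective gating charge net_charge · delta / field_drop_distance, in e.

    ``delta`` is the center-of-charge shift (Å) and ``field_drop_distance``
    the distance (Å) over which the membrane field falls; a full traversal
    of the field region by the whole net charge counts as that many
    elementary charges.
    """
    if field_drop_distance <= 0:
        raise ValueError(
            f"field_drop_distance must be > 0, got {field_drop_distance}"
        )
    return net_charge * delta / field_drop_distance
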