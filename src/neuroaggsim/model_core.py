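"""Force laws, movement-freedom schedule and equilibrium analysis.

The aggregation model treats every cell as a point object subject to three
exponentially decaying pairwise interactions:

* **attraction** between cells, scaled by a type-pair constant (the four
  ``AS`` values for neuron/astrocyte combinations),
* **repulsion** between cells, identical for all cell types,
* **surface adhesion** pulling cells toward fixed anchoring points on the
  substrate plane,

plus a constant downward gravity displacement per step.  Each force has a
strength and a length constant; the length constant is the distance at which
the force has dropped to 1% of its maximum, i.e.

    F(d) = strength * 0.01**(d / tau)

The pairwise attraction/repulsion balance defines a *force equilibrium
point*: the separation at which attraction and repulsion cancel, which sets
the characteristic cell-to-cell distance of the aggregated culture.

A time-dependent *movement freedom* factor k(t) in [0, 1] scales all
force-driven displacement; it decays sigmoidally from 1 toward 0 around a
stiffening delay, modeling the halt of aggregation as the culture matures.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CellType",
    "ForceParameters",
    "StiffnessSchedule",
    "PRESETS",
    "get_preset",
    "force_magnitude",
    "net_force",
    "movement_freedom",
    "displace",
    "equilibrium_distance",
    "repulsion_for_equilibrium",
]

#: decade constant: exponent base of every force law
LN001 = math.log(0.01)


class CellType(enum.IntEnum):
    """Mobile cell species in the model."""

    NEURON = 0
    ASTROCYTE = 1


_PAIR_KEYS = (("N", "N"), ("N", "A"), ("A", "N"), ("A", "A"))


@dataclass(frozen=True)
class ForceParameters:
    """Strengths and length constants of the three force laws.

    Parameters
    ----------
    A, tau_a
        Attraction strength (dimensionless force units) and length constant
        (um).
    R, tau_r
        Repulsion strength and length constant (um).  Repulsion is identical
        for all cell-type pairs.
    S, tau_s
        Surface-adhesion strength and length constant (um).
    AS
        Type-pair attraction constants, keyed by ``(i_type, j_type)`` where
        the first element is the cell feeling the force, e.g. ``("N", "A")``
        is the attraction felt by a neuron due to an astrocyte.
    g
        Constant per-step downward displacement (um/step), not scaled by the
        movement-freedom factor.
    """

    A: float = 1.0
    tau_a: float = 320.0
    R: float = 2.27
    tau_r: float = 200.0
    S: float = 0.01
    tau_s: float = 30.0
    AS: dict = field(
        default_factory=lambda: {
            ("N", "N"): 1.0,
            ("N", "A"): 0.9,
            ("A", "N"): 0.8,
            ("A", "A"): 0.7,
        }
    )
    g: float = 1e-4

    def __post_init__(self):
        for name in ("A", "R", "S"):
            if getattr(self, name) < 0:
                raise ValueError(f"force strength {name} must be >= 0")
        for name in ("tau_a", "tau_r", "tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"length constant {name} must be > 0")
        if set(self.AS) != set(_PAIR_KEYS):
            raise ValueError(
                f"AS must have exactly the keys {_PAIR_KEYS}, got {sorted(self.AS)}"
            )
        if self.g < 0:
            raise ValueError("gravity g must be >= 0")

    def as_matrix(self) -> np.ndarray:
        """AS constants as a 2x2 array indexed by (CellType_i, CellType_j)."""
        tags = ("N", "A")
        out = np.empty((2, 2))
        for i, ti in enumerate(tags):
            for j, tj in enumerate(tags):
                out[i, j] = self.AS[(ti, tj)]
        return out

    def with_AS(self, nn: float, na: float, an: float, aa: float) -> "ForceParameters":
        return replace(
            self,
            AS={("N", "N"): nn, ("N", "A"): na, ("A", "N"): an, ("A", "A"): aa},
        )

    # --- flat-dict serialization (YAML/JSON config section) ---------------

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "tau_a": self.tau_a,
            "R": self.R,
            "tau_r": self.tau_r,
            "S": self.S,
            "tau_s": self.tau_s,
            "g": self.g,
            "AS_NN": self.AS[("N", "N")],
            "AS_NA": self.AS[("N", "A")],
            "AS_AN": self.AS[("A", "N")],
            "AS_AA": self.AS[("A", "A")],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceParameters":
        d = dict(d)
        AS = {
            ("N", "N"): float(d.pop("AS_NN")),
            ("N", "A"): float(d.pop("AS_NA")),
            ("A", "N"): float(d.pop("AS_AN")),
            ("A", "A"): float(d.pop("AS_AA")),
        }
        return cls(AS=AS, **{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class StiffnessSchedule:
    """Timing of the movement-freedom (stiffening) sigmoid.

    ``movement_freedom`` is 0.5 at ``stiffening_delay`` and decays over a
    timescale ``stiffening_constant``; the run lasts ``total_time`` steps.
    """

    total_time: int = 350
    stiffening_delay: float = 300.0
    stiffening_constant: float = 20.0

    def __post_init__(self):
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")
        if self.stiffening_constant <= 0:
            raise ValueError("stiffening_constant must be > 0")

    def to_dict(self) -> dict:
        return {
            "total_time": self.total_time,
            "stiffening_delay": self.stiffening_delay,
            "stiffening_constant": self.stiffening_constant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StiffnessSchedule":
        return cls(
            total_time=int(d["total_time"]),
            stiffening_delay=float(d["stiffening_delay"]),
            stiffening_constant=float(d["stiffening_constant"]),
        )


# Named parameter presets; they differ only in the repulsion length constant.
PRESETS: dict[str, tuple[ForceParameters, StiffnessSchedule]] = {
    "initial": (ForceParameters(tau_r=140.0), StiffnessSchedule()),
    "optimized": (ForceParameters(tau_r=200.0), StiffnessSchedule()),
}


def get_preset(name: str) -> tuple[ForceParameters, StiffnessSchedule]:
    """Return (ForceParameters, StiffnessSchedule) for a named preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def force_magnitude(d, strength: float, tau: float):
    """Exponential force magnitude ``strength * 0.01**(d / tau)``.

    ``tau`` is the distance at which the force drops to 1% of its maximum.
    Accepts scalar or array distances.
    """
    if tau <= 0:
        raise ValueError("length constant tau must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = strength * np.exp(LN001 / tau * d)
    return float(out) if out.ndim == 0 else out


def movement_freedom(t, schedule: StiffnessSchedule):
    """Movement-freedom factor k(t) = 1 - sigma((t - delay)/constant).

    Starts near 1, passes through 0.5 at the stiffening delay and decays
    toward 0, freezing the culture.  Accepts scalar or array ``t``.
    """
    z = (np.asarray(t, dtype=float) - schedule.stiffening_delay) / schedule.stiffening_constant
    z = np.clip(z, -700.0, 700.0)  # exp overflow guard; k saturates anyway
    # 1 - e^z/(1+e^z) = 1/(1+e^z), computed stably on both tails
    k = np.where(z > 0, np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))), 1.0 / (1.0 + np.exp(np.minimum(z, 0))))
    return float(k) if k.ndim == 0 else k


def displace(force, k: float, g: float) -> np.ndarray:
    """One-step displacement (dx, dy, dz) = (k*Fx, k*Fy, k*Fz - g).

    Gravity acts as a constant downward displacement and is not scaled by
    the movement-freedom factor.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError("movement freedom k must lie in [0, 1]")
    f = np.asarray(force, dtype=float)
    out = k * f
    out[..., 2] -= g
    return out


def net_force(
    i: int,
    positions: np.ndarray,
    types: np.ndarray,
    anchors: np.ndarray | None,
    params: ForceParameters,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Total force on cell ``i`` from all other cells and all anchors.

    Reference (vectorized-numpy) implementation used for small systems and
    as the oracle for the compiled engine.  Attraction pulls toward each
    other cell with magnitude ``AS[type_i, type_j] * A * 0.01**(d/tau_a)``,
    repulsion pushes away with magnitude ``R * 0.01**(d/tau_r)``, and each
    anchor on the substrate plane attracts with magnitude
    ``S * 0.01**(d/tau_s)``, all along the 3D unit separation vector with
    d the Euclidean distance.

    Coincident distinct cells (d = 0) receive the full repulsion magnitude
    along a random unit vector (attraction contributes nothing there); pass
    ``rng`` to make that tie-break reproducible.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n == 0:
        raise ValueError("population is empty")
    if not 0 <= i < n:
        raise IndexError(f"cell index {i} out of range for {n} cells")
    types = np.asarray(types, dtype=int)
    as_mat = params.as_matrix()

    f = np.zeros(3)
    mask = np.arange(n) != i
    if mask.any():
        diff = positions[mask] - positions[i]
        d = np.linalg.norm(diff, axis=1)
        ok = d > 0
        if ok.any():
            u = diff[ok] / d[ok, None]
            attr = as_mat[types[i], types[mask][ok]] * force_magnitude(d[ok], params.A, params.tau_a)
            rep = force_magnitude(d[ok], params.R, params.tau_r)
            f += ((attr - rep)[:, None] * u).sum(axis=0)
        n_coincident = int((~ok).sum())
        if n_coincident:
            rng = np.random.default_rng() if rng is None else rng
            for _ in range(n_coincident):
                v = rng.standard_normal(3)
                f -= params.R * v / np.linalg.norm(v)
    if anchors is not None and len(anchors):
        anchors = np.asarray(anchors, dtype=float)
        a3 = np.zeros((anchors.shape[0], 3))
        a3[:, :2] = anchors[:, :2]
        diff = a3 - positions[i]
        d = np.linalg.norm(diff, axis=1)
        ok = d > 0
        if ok.any():
            u = diff[ok] / d[ok, None]
            adh = force_magnitude(d[ok], params.S, params.tau_s)
            f += (adh[:, None] * u).sum(axis=0)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError(f"non-finite force on cell {i}")
    return f


def equilibrium_distance(A_eff: float, tau_a: float, R: float, tau_r: float) -> float:
    """Separation d* at which attraction and repulsion magnitudes are equal.

    Solves ``A_eff * 0.01**(d/tau_a) == R * 0.01**(d/tau_r)``:

        d* = ln(R / A_eff) / (ln(0.01) * (1/tau_a - 1/tau_r))

    Raises if the two exponentials do not cross at a unique non-negative
    distance (equal length constants, or parameters implying d* < 0).
    """
    if A_eff <= 0 or R <= 0:
        raise ValueError("A_eff and R must be > 0")
    if tau_a <= 0 or tau_r <= 0:
        raise ValueError("length constants must be > 0")
    if tau_a == tau_r:
        raise ValueError(
            "tau_a == tau_r: the force curves are proportional and have no "
            "unique equilibrium point"
        )
    d = math.log(R / A_eff) / (LN001 * (1.0 / tau_a - 1.0 / tau_r))
    if d < 0:
        raise ValueError(
            f"parameters imply a negative equilibrium distance ({d:.3g} um)"
        )
    return d


def repulsion_for_equilibrium(target_d: float, A_eff: float, tau_a: float, tau_r: float) -> float:
    """Repulsion strength R that places the force equilibrium at ``target_d``.

    Exact inverse of :func:`equilibrium_distance`:

        R = A_eff * 0.01**(target_d * (1/tau_a - 1/tau_r))
    """
    if target_d < 0:
        raise ValueError("target equilibrium distance must be >= 0")
    if A_eff <= 0:
        raise ValueError("A_eff must be > 0")
    if tau_a <= 0 or tau_r <= 0:
        raise ValueError("length constants must be > 0")
    if tau_a == tau_r and target_d != 0:
        raise ValueError("tau_a == tau_r admits no equilibrium at a positive distance")
    return A_eff * math.exp(LN001 * target_d * (1.0 / tau_a - 1.0 / tau_r))
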