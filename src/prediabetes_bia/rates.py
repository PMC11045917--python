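"""Annual-to-monthly transition conversion and intervention risk reductions.

The model is specified with annual transition probabilities between four
health states (normoglycemia, prediabetes, T2D, death) but runs in monthly
cycles. The monthly matrix is the 12th root of the annual row-stochastic
matrix, taken via eigen decomposition: if A = V diag(w) V^-1 with real,
positive eigenvalues, then M = V diag(w^(1/12)) V^-1 satisfies M^12 = A.
The root of a stochastic matrix can carry tiny negative entries (the
discrete embedding problem); these are clipped to zero and the row is
renormalised, which perturbs the round trip by well under 1e-6 for the
matrices in this model's parameter space.

Scalar adherence probabilities (annual defaulting/compliance) use the
constant-hazard equivalent 1 - (1-p)^(1/12), which coincides with the
matrix root of the corresponding two-state chain.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: canonical health-state order used by every matrix and mass vector
STATES = ("normoglycemia", "prediabetes", "t2d", "death")
N_STATES = len(STATES)
NORMO, PRE, T2D, DEATH = range(N_STATES)


@dataclass(frozen=True)
class AnnualTransitionSet:
    """Annual transition probabilities between health states.

    Defaults are the model's base case: prediabetes regresses to
    normoglycemia at 45%/yr (scenario values 15%/30%/45%), progresses to
    T2D at 7.5%/yr, and T2D is irreversible except through death.
    """

    p_norm_to_pre: float = 0.015
    p_norm_to_t2d: float = 0.0072
    p_norm_to_death: float = 0.011
    p_pre_to_norm: float = 0.45
    p_pre_to_t2d: float = 0.075
    p_pre_to_death: float = 0.012
    p_t2d_to_norm: float = 0.0
    p_t2d_to_pre: float = 0.0
    p_t2d_to_death: float = 0.03

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name}={v} outside [0, 1]")
        outflows = {
            "normoglycemia": self.p_norm_to_pre + self.p_norm_to_t2d + self.p_norm_to_death,
            "prediabetes": self.p_pre_to_norm + self.p_pre_to_t2d + self.p_pre_to_death,
            "t2d": self.p_t2d_to_norm + self.p_t2d_to_pre + self.p_t2d_to_death,
        }
        for state, total in outflows.items():
            if total > 1.0 + 1e-12:
                raise ValueError(f"annual outflow from {state} sums to {total} > 1")


@dataclass(frozen=True)
class TreatmentEffect:
    """Two-regime annual T2D risk reduction on prediabetes -> T2D.

    ``rr_early`` applies while time on model is at most 3 years (months
    1-36), ``rr_late`` afterwards, mirroring the trial's 3-year and longer
    term incidence reductions.
    """

    rr_early: float
    rr_late: float

    def __post_init__(self) -> None:
        for name in ("rr_early", "rr_late"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def at_month(self, month: int) -> float:
        return self.rr_early if month <= 36 else self.rr_late

    def scaled(self, multiplier: float) -> "TreatmentEffect":
        """Multiply both regimes, capping each at 1 (used by the OWSA)."""
        return TreatmentEffect(
            rr_early=min(1.0, self.rr_early * multiplier),
            rr_late=min(1.0, self.rr_late * multiplier),
        )


#: trial-derived effects: metformin (ER) 31%/18%, intensive lifestyle change 58%/34%
METFORMIN_EFFECT = TreatmentEffect(rr_early=0.31, rr_late=0.18)
ILC_EFFECT = TreatmentEffect(rr_early=0.58, rr_late=0.34)


def build_annual_matrix(t: AnnualTransitionSet) -> np.ndarray:
    """Row-stochastic annual matrix in :data:`STATES` order; death absorbing."""
    a = np.zeros((N_STATES, N_STATES))
    a[NORMO, PRE] = t.p_norm_to_pre
    a[NORMO, T2D] = t.p_norm_to_t2d
    a[NORMO, DEATH] = t.p_norm_to_death
    a[PRE, NORMO] = t.p_pre_to_norm
    a[PRE, T2D] = t.p_pre_to_t2d
    a[PRE, DEATH] = t.p_pre_to_death
    a[T2D, NORMO] = t.p_t2d_to_norm
    a[T2D, PRE] = t.p_t2d_to_pre
    a[T2D, DEATH] = t.p_t2d_to_death
    np.fill_diagonal(a, 1.0 - a.sum(axis=1))
    a[DEATH] = 0.0
    a[DEATH, DEATH] = 1.0
    return a


def matrix_root_monthly(annual: np.ndarray, cycles_per_year: int = 12) -> np.ndarray:
    """Monthly transition matrix M with M**cycles_per_year == annual.

    Raises ``ValueError`` when the input is not row-stochastic or its
    eigenvalues are complex or non-positive (no admissible real root under
    this method).
    """
    annual = np.asarray(annual, dtype=float)
    if annual.ndim != 2 or annual.shape[0] != annual.shape[1]:
        raise ValueError("annual matrix must be square")
    if np.any(annual < -1e-12) or np.any(np.abs(annual.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("annual matrix must be row-stochastic")

    w, v = np.linalg.eig(annual)
    if np.any(np.abs(w.imag) > 1e-12) or np.any(w.real <= 0):
        raise ValueError("annual matrix has complex or non-positive eigenvalues; "
                         "no real monthly root via eigen decomposition")
    root = (v * np.power(w.real, 1.0 / cycles_per_year)) @ np.linalg.inv(v)
    root = np.real(root)

    raw_err = np.max(np.abs(np.linalg.matrix_power(root, cycles_per_year) - annual))
    if raw_err > 1e-8:
        raise ValueError(f"eigen root inaccurate: round-trip error {raw_err:.2e}")

    # embedding repair: clip negatives, renormalise rows. Within the model's
    # parameter space negatives are below 1e-6 and the repaired round trip
    # still holds to 1e-6; boundary matrices with an exactly-zero transition
    # that two-step paths would recreate (e.g. full protection) have no
    # nonnegative root, and the clipped matrix is the admissible approximation.
    negative = -root[root < 0].sum() if np.any(root < 0) else 0.0
    if negative > 1e-6:
        logger.warning(
            "monthly root clipped negative mass %.2e; annual matrix is at the "
            "edge of embeddability", negative,
        )
    root[root < 0] = 0.0
    root /= root.sum(axis=1, keepdims=True)
    # keep absorbing rows exact
    for i in range(annual.shape[0]):
        if annual[i, i] == 1.0 and annual[i].sum() == 1.0:
            root[i] = 0.0
            root[i, i] = 1.0
    return root


def scalar_prob_to_monthly(p_annual: float, cycles_per_year: int = 12) -> float:
    """Constant-hazard monthly equivalent of an annual probability."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"probability {p_annual} outside [0, 1]")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def apply_risk_reduction(t: AnnualTransitionSet, rr: float) -> AnnualTransitionSet:
    """Scale the annual prediabetes -> T2D probability by (1 - rr).

    The freed probability mass accrues to the prediabetes diagonal when the
    matrix is rebuilt; all other transitions are untouched.
    """
    if not 0.0 <= rr <= 1.0:
        raise ValueError(f"risk reduction {rr} outside [0, 1]")
    return dataclasses.replace(t, p_pre_to_t2d=t.p_pre_to_t2d * (1.0 - rr))
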