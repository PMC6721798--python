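"""Three-state occupancy model of dual translational repression of FTL mRNA.

The ferritin light chain (*FTL*) 5'-UTR carries two adjacent repressive
elements: the iron-responsive element (IRE), bound by iron regulatory
proteins (IRPs), and an eIF3 repressive element immediately downstream.
Under the hypothesis that IRP and eIF3 never occupy the same transcript,
the mRNA pool splits into three states -- bound solely by IRP (``x1``),
bound solely by eIF3 (``x2``), and free (``x3``) -- translating with
efficiencies ``y1``, ``y2`` and 1 respectively.  A mutation that abolishes
the eIF3 site redistributes a fraction ``alpha`` of the eIF3-bound pool,
and a mutation that abolishes IRP binding redistributes a fraction
``beta`` of the IRP-bound pool, with ``0 <= alpha + beta <= 1``.

Normalising the wild-type reporter readout to 1 eliminates ``x3`` and
yields reduced predictions for the three mutant reporters:

    d3re   = 1 + y1*alpha - alpha + (1 - y2)*x2
    loop   = 1 + y2*beta  - beta  + (1 - y1)*x1
    double = 1 + (1 - y1)*x1 + (1 - y2)*x2

which satisfy the identity

    double = loop + d3re + (alpha + beta - y1*alpha - y2*beta - 1)

The bracketed term is confined to [-1, 0] over the whole constrained
parameter box, so the exclusive-binding model is feasible only when the
measured Double readout does not exceed Loop + d3re.  Measured reporter
data that violate this bound falsify the hypothesis and imply that the
two repressors can act in cis on the same transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize
from scipy.stats import chi2, qmc

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyParams",
    "Readout",
    "ConstructReadouts",
    "ExclusivityVerdict",
    "FeasibilityReport",
    "RawPredictions",
    "ReducedPredictions",
    "predict_raw",
    "predict_reduced",
    "bracket_term",
    "rhs_bounds",
    "test_exclusivity",
    "fit_exclusive",
    "pooled_sd",
    "canonical_construct",
    "fold_change",
]

#: canonical reporter construct names
CONSTRUCTS = ("FTL", "DPAR", "D3RE", "LOOP", "DOUBLE", "G51C", "G52C")

#: constructs required by the exclusivity test
EXCLUSIVITY_CONSTRUCTS = ("D3RE", "LOOP", "DOUBLE")

_ALIAS = {
    "WT": "FTL",
    "WTFTL": "FTL",
    "FTLWT": "FTL",
    "DPARCLIP": "DPAR",
    "PAR": "DPAR",
}


class ConstraintError(ValueError):
    """A model parameter violates a named constraint."""


def canonical_construct(name: str) -> str:
    """Map a free-form construct label onto its canonical name.

    Accepts case-insensitive names with Greek deltas ("Δ3RE", "∆PAR") or
    spelled-out deltas ("delta3RE"); raises :class:`ConstraintError` for
    labels outside the known construct set.
    """
    key = str(name).strip().upper()
    for delta in ("Δ", "∆"):
        key = key.replace(delta, "D")
    key = key.replace("DELTA", "D")
    key = key.replace(" ", "").replace("-", "").replace("_", "")
    key = _ALIAS.get(key, key)
    if key not in CONSTRUCTS:
        raise ConstraintError(
            f"unknown construct {name!r}; expected one of {', '.join(CONSTRUCTS)}"
        )
    return key


class OccupancyParams(BaseModel):
    """State of the exclusive-binding occupancy model.

    ``x3`` may be omitted (``None``) for parameter sets living in the
    reduced model, where the free fraction has been eliminated through the
    wild-type normalisation ``x3 = 1 - y1*x1 - y2*x2``.  When ``x3`` is
    given explicitly the simplex constraint ``x1 + x2 + x3 = 1`` is
    enforced.
    """

    model_config = ConfigDict(frozen=True)

    x1: float = Field(ge=0, description="fraction bound solely by IRP")
    x2: float = Field(ge=0, description="fraction bound solely by eIF3")
    x3: float | None = Field(default=None, ge=0, description="unbound fraction")
    y1: float = Field(ge=0, le=1, description="translational efficiency, IRP-bound")
    y2: float = Field(ge=0, le=1, description="translational efficiency, eIF3-bound")
    alpha: float = Field(default=0.0, ge=0, description="redistribution on eIF3-site loss")
    beta: float = Field(default=0.0, ge=0, description="redistribution on IRP-site loss")

    @model_validator(mode="after")
    def _check_joint_constraints(self) -> "OccupancyParams":
        if self.alpha + self.beta > 1 + 1e-12:
            raise ValueError(
                f"alpha + beta = {self.alpha + self.beta:.6g} violates alpha + beta <= 1"
            )
        if self.x3 is not None:
            total = self.x1 + self.x2 + self.x3
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"x1 + x2 + x3 = {total:.6g} violates the simplex constraint (= 1)"
                )
        return self


class RawPredictions(NamedTuple):
    """Predicted normalized reporter outputs of the full three-state model."""

    ftl: float
    d3re: float
    loop: float
    double: float


class ReducedPredictions(NamedTuple):
    """Predicted mutant outputs after eliminating the free fraction (FTL = 1)."""

    d3re: float
    loop: float
    double: float


def predict_raw(params: OccupancyParams) -> RawPredictions:
    """Predict the four reporter outputs from an explicit three-state split.

    Requires ``x3``; the wild-type output is ``y1*x1 + y2*x2 + x3`` and the
    mutant outputs shift the affected bound pools into the competing or free
    states by ``alpha`` / ``beta``.
    """
    if params.x3 is None:
        raise ConstraintError("predict_raw requires an explicit x3 (free fraction)")
    x1, x2, x3 = params.x1, params.x2, params.x3
    y1, y2, a, b = params.y1, params.y2, params.alpha, params.beta
    return RawPredictions(
        ftl=y1 * x1 + y2 * x2 + x3,
        d3re=y1 * (x1 + a) + x2 - a + x3,
        loop=x1 - b + y2 * (x2 + b) + x3,
        double=x1 + x2 + x3,
    )


def predict_reduced(params: OccupancyParams) -> ReducedPredictions:
    """Predict the mutant outputs in the reduced (WT-normalised) model.

    The wild-type readout is fixed at 1 and the free fraction eliminated via
    ``x3 = 1 - y1*x1 - y2*x2``; only ``x1, x2, y1, y2, alpha, beta`` enter.
    """
    x1, x2 = params.x1, params.x2
    y1, y2, a, b = params.y1, params.y2, params.alpha, params.beta
    return ReducedPredictions(
        d3re=1.0 + y1 * a - a + (1.0 - y2) * x2,
        loop=1.0 + y2 * b - b + (1.0 - y1) * x1,
        double=1.0 + (1.0 - y1) * x1 + (1.0 - y2) * x2,
    )


def _check_box(y1: float, y2: float, alpha: float, beta: float) -> None:
    if not 0.0 <= y1 <= 1.0:
        raise ConstraintError(f"y1 = {y1:.6g} violates 0 <= y1 <= 1")
    if not 0.0 <= y2 <= 1.0:
        raise ConstraintError(f"y2 = {y2:.6g} violates 0 <= y2 <= 1")
    if alpha < 0:
        raise ConstraintError(f"alpha = {alpha:.6g} violates alpha >= 0")
    if beta < 0:
        raise ConstraintError(f"beta = {beta:.6g} violates beta >= 0")
    if alpha + beta > 1 + 1e-12:
        raise ConstraintError(
            f"alpha + beta = {alpha + beta:.6g} violates alpha + beta <= 1"
        )


def bracket_term(y1: float, y2: float, alpha: float, beta: float) -> float:
    """The residual term ``alpha + beta - y1*alpha - y2*beta - 1``.

    This is the exact difference ``double - loop - d3re`` of the reduced
    predictions; over the constrained box it ranges between -1 (no
    redistribution) and 0 (full redistribution of fully repressed pools).
    """
    _check_box(y1, y2, alpha, beta)
    return alpha + beta - y1 * alpha - y2 * beta - 1.0


def rhs_bounds(loop_mean: float, d3re_mean: float) -> tuple[float, float]:
    """Feasible range of the Double readout under exclusive binding.

    Given measured Loop and d3re means, the model predicts
    ``double = loop + d3re + bracket`` with the bracket in [-1, 0]; the
    feasible Double interval is therefore
    ``(loop + d3re - 1, loop + d3re)``.
    """
    if loop_mean <= 0 or d3re_mean <= 0:
        raise ConstraintError("construct means must be positive")
    upper = loop_mean + d3re_mean
    return upper - 1.0, upper


def pooled_sd(*sds: float) -> float:
    """Quadrature (root-sum-square) combination of independent SDs."""
    return float(np.sqrt(sum(s * s for s in sds)))


@dataclass(frozen=True)
class Readout:
    """Mean normalized luciferase readout of one construct."""

    mean: float
    sd: float
    n: int = 1

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ConstraintError(f"readout mean must be > 0, got {self.mean!r}")
        if self.sd < 0:
            raise ConstraintError(f"readout sd must be >= 0, got {self.sd!r}")
        if self.n < 1:
            raise ConstraintError(f"replicate count must be >= 1, got {self.n!r}")


@dataclass
class ConstructReadouts:
    """Per-construct normalized luciferase readouts (WT FTL == 1)."""

    entries: dict[str, Readout] = field(default_factory=dict)

    @classmethod
    def from_means(cls, data: Mapping[str, tuple[float, float, int]]) -> "ConstructReadouts":
        """Build from ``{construct: (mean, sd, n)}``."""
        return cls(
            {canonical_construct(k): Readout(*v) for k, v in data.items()}
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ConstructReadouts":
        """Summarise a replicate-level reporter table (construct, value)."""
        entries = {}
        for name, grp in table.groupby("construct"):
            vals = np.asarray(grp["value"], dtype=float)
            entries[canonical_construct(str(name))] = Readout(
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                n=len(vals),
            )
        return cls(entries)

    def __getitem__(self, name: str) -> Readout:
        return self.entries[canonical_construct(name)]

    def __contains__(self, name: str) -> bool:
        try:
            return canonical_construct(name) in self.entries
        except ConstraintError:
            return False

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if canonical_construct(n) not in self.entries]
        if missing:
            raise ConstraintError(
                f"missing construct(s) {', '.join(missing)}; "
                f"present: {', '.join(sorted(self.entries))}"
            )


def fold_change(table: pd.DataFrame, construct: str, reference: str = "FTL") -> float:
    """Mean fold change of `construct` over `reference` in a replicate table."""
    ro = ConstructReadouts.from_table(table)
    ro.require([construct, reference])
    return ro[construct].mean / ro[reference].mean


@dataclass(frozen=True)
class ExclusivityVerdict:
    """Outcome of testing the exclusive-binding model against reporter data."""

    rhs_lower: float
    rhs_upper: float
    point_consistent: bool
    p_consistent: float
    z_score: float
    n_draws: int
    seed: int

    #: significance level below which the model is declared inconsistent
    ALPHA = 0.05

    @property
    def inconsistent(self) -> bool:
        return self.p_consistent < self.ALPHA

    def to_dict(self) -> dict:
        return {
            "rhs_lower": self.rhs_lower,
            "rhs_upper": self.rhs_upper,
            "point_consistent": self.point_consistent,
            "p_consistent": self.p_consistent,
            "z_score": self.z_score,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "verdict": "inconsistent" if self.inconsistent else "consistent",
        }


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws with negative values resampled (readouts are positive)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def test_exclusivity(
    readouts: ConstructReadouts,
    n_draws: int = 100_000,
    seed: int = 2019,
) -> ExclusivityVerdict:
    """Test whether measured readouts are consistent with exclusive binding.

    The point test checks ``double <= loop + d3re`` (the upper feasibility
    bound).  Measurement error is propagated by Monte Carlo: each
    construct's mean is resampled from an independent normal with its
    reported SD, truncated at zero, and ``p_consistent`` is the fraction of
    draws satisfying the inequality.  ``z_score`` is the Gaussian-propagated
    standardized exceedance of the bound.

    Deterministic for a fixed ``seed``.
    """
    readouts.require(EXCLUSIVITY_CONSTRUCTS)
    if n_draws < 1:
        raise ConstraintError("n_draws must be >= 1")
    if n_draws < 1000:
        logger.warning(
            "n_draws = %d is below 1000; Monte-Carlo error on p_consistent "
            "will be substantial", n_draws,
        )
    d3re, loop, double = readouts["D3RE"], readouts["LOOP"], readouts["DOUBLE"]
    rhs_lower, rhs_upper = rhs_bounds(loop.mean, d3re.mean)
    point_consistent = bool(double.mean <= rhs_upper)

    rng = np.random.default_rng(seed)
    draws_d3re = _truncated_normal(rng, d3re.mean, d3re.sd, n_draws)
    draws_loop = _truncated_normal(rng, loop.mean, loop.sd, n_draws)
    draws_double = _truncated_normal(rng, double.mean, double.sd, n_draws)
    p_consistent = float(np.mean(draws_double <= draws_loop + draws_d3re))

    denom = pooled_sd(double.sd, loop.sd, d3re.sd)
    z = (double.mean - loop.mean - d3re.mean) / denom if denom > 0 else np.inf
    return ExclusivityVerdict(
        rhs_lower=rhs_lower,
        rhs_upper=rhs_upper,
        point_consistent=point_consistent,
        p_consistent=p_consistent,
        z_score=float(z),
        n_draws=n_draws,
        seed=seed,
    )


@dataclass(frozen=True)
class FeasibilityReport:
    """Best constrained fit of the exclusive model to mutant readouts."""

    params: OccupancyParams
    chi_square: float
    feasible: bool
    converged: bool
    predicted: ReducedPredictions
    n_starts: int

    def to_dict(self) -> dict:
        return {
            "params": self.params.model_dump(),
            "chi_square": self.chi_square,
            "feasible": self.feasible,
            "converged": self.converged,
            "predicted": self.predicted._asdict(),
            "n_starts": self.n_starts,
        }


#: upper bound used for the rescaled bound fractions during fitting; mutant
#: readouts up to ~40-fold over WT are reachable well inside this box
_X_MAX = 50.0
_SD_FLOOR = 1e-6


def fit_exclusive(
    readouts: ConstructReadouts,
    n_starts: int = 32,
    chi2_quantile: float = 0.95,
) -> FeasibilityReport:
    """Search the constrained box for parameters reproducing the readouts.

    Minimizes the SD-weighted squared residual of the reduced-model
    predictions against the measured d3re/Loop/Double means over
    ``(x1, x2) in [0, 50]^2, (y1, y2) in [0, 1]^2, alpha, beta >= 0,
    alpha + beta <= 1`` using multi-start SLSQP seeded from a Latin
    hypercube.  The model is *feasible* when the minimized chi-square does
    not exceed the ``chi2_quantile`` point of chi-square with 3 degrees of
    freedom.  Since the parameter-to-readout map is not injective, only the
    predicted outputs (not the minimizing parameters) are identifiable.
    """
    readouts.require(EXCLUSIVITY_CONSTRUCTS)
    means = np.array([readouts[c].mean for c in EXCLUSIVITY_CONSTRUCTS])
    sds = np.array([max(readouts[c].sd, _SD_FLOOR) for c in EXCLUSIVITY_CONSTRUCTS])

    def predict(theta: np.ndarray) -> np.ndarray:
        x1, x2, y1, y2, a, b = theta
        return np.array([
            1.0 + y1 * a - a + (1.0 - y2) * x2,
            1.0 + y2 * b - b + (1.0 - y1) * x1,
            1.0 + (1.0 - y1) * x1 + (1.0 - y2) * x2,
        ])

    def objective(theta: np.ndarray) -> float:
        r = (predict(theta) - means) / sds
        return float(r @ r)

    bounds = [(0.0, _X_MAX), (0.0, _X_MAX), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0)]
    constraint = {"type": "ineq", "fun": lambda th: 1.0 - th[4] - th[5]}

    sampler = qmc.LatinHypercube(d=6, seed=7)
    starts = sampler.random(n_starts)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = lo + starts * (hi - lo)
    # project starts into alpha + beta <= 1
    ab = starts[:, 4] + starts[:, 5]
    over = ab > 1.0
    starts[over, 4:6] /= ab[over, None] * (1 + 1e-9)

    best_theta: np.ndarray | None = None
    best_chi2 = np.inf
    any_converged = False
    for theta0 in starts:
        res = optimize.minimize(
            objective,
            theta0,
            method="SLSQP",
            bounds=bounds,
            constraints=[constraint],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        any_converged = any_converged or bool(res.success)
        cand = np.clip(res.x, lo, hi)
        chi = objective(cand)
        # ties broken by lowest chi-square, then lexicographic parameter order
        if chi < best_chi2 - 1e-15 or (
            abs(chi - best_chi2) <= 1e-15
            and best_theta is not None
            and tuple(cand) < tuple(best_theta)
        ):
            best_chi2 = chi
            best_theta = cand

    if best_theta is None:  # pragma: no cover - minimize always returns a point
        raise RuntimeError("optimizer produced no candidate point")
    if not any_converged:
        logger.warning("fit_exclusive: no optimizer start converged; reporting best point found")

    x1, x2, y1, y2, a, b = (float(v) for v in best_theta)
    params = OccupancyParams(x1=x1, x2=x2, x3=None, y1=y1, y2=y2, alpha=a, beta=b)
    threshold = chi2.ppf(chi2_quantile, df=3)
    return FeasibilityReport(
        params=params,
        chi_square=best_chi2,
        feasible=bool(best_chi2 <= threshold),
        converged=any_converged,
        predicted=ReducedPredictions(*predict(best_theta)),
        n_starts=n_starts,
    )
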