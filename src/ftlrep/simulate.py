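"""Synthetic data generators for every pipeline input.

No raw measurements from the reporter or gel-shift experiments are
publicly deposited, so this module generates them from the published
summary quantities: reporter tables at the printed effect sizes (38-fold
derepression for the Delta-PAR deletion, six-fold for Delta-3RE, strong
synergy of the Double mutant), and EMSA time courses / dose-response
tables from the mass-action competition simulator at the printed
k_off of 0.006 min^-1 and protocol concentrations.

Noise models: luminescence replicates get multiplicative log-normal noise
(luminescence is strictly positive and spans a 40-fold range), gel-derived
bound fractions get additive Gaussian noise clipped to [0, 1]
(densitometry is background-subtracted).  All generators are pure
functions of (parameters, seed).
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .kinetics import BindingReaction, DoseResponse, TimeCourse, simulate_competition
from .occupancy import OccupancyParams, canonical_construct, predict_raw

__all__ = [
    "ReporterGenParams",
    "gen_reporter",
    "gen_timecourse",
    "gen_dose_response",
    "gen_utr",
    "cobinding_means",
]

#: printed fold-derepression effect sizes used as generator defaults
DEFAULT_FOLD_TARGETS = {"DPAR": 38.0, "D3RE": 6.0}


class ReporterGenParams(BaseModel):
    """Configuration for generating a replicate-level reporter table.

    Three generative modes:

    * ``exclusive`` -- construct means from the three-state occupancy model
      (IRP and eIF3 never co-bound).
    * ``cobinding`` -- a four-state alternative with a doubly-bound
      fraction ``x4`` translating at ``y1 * y2`` (independent repression;
      configurable to ``min(y1, y2)``).  This rule is an explicit modeling
      assumption of the generator, not a measured mechanism.
    * ``fold_override`` -- construct means set directly from
      ``fold_targets`` (WT = 1), e.g. the printed 38-fold Delta-PAR and
      six-fold Delta-3RE derepressions.
    """

    model_config = ConfigDict(frozen=True)

    mode: Literal["exclusive", "cobinding", "fold_override"] = "exclusive"
    params: OccupancyParams | None = None
    x4: float = Field(default=0.0, ge=0, description="co-bound fraction (cobinding mode)")
    cobinding_rule: Literal["product", "min"] = "product"
    fold_targets: dict[str, float] | None = None
    n: int = Field(default=100, ge=1, description="replicates per construct")
    cv: float = Field(default=0.10, ge=0, description="coefficient of variation")
    seed: int = 2019

    @model_validator(mode="after")
    def _check(self) -> "ReporterGenParams":
        if self.mode == "fold_override":
            targets = self.fold_targets or DEFAULT_FOLD_TARGETS
            if any(v <= 0 for v in targets.values()):
                raise ValueError("fold targets must be positive")
        else:
            if self.params is None:
                raise ValueError(f"mode {self.mode!r} requires occupancy params")
            if self.mode == "cobinding":
                free = 1.0 - self.params.x1 - self.params.x2 - self.x4
                if free < -1e-12:
                    raise ValueError(
                        "x1 + x2 + x4 exceeds 1; no mass left for the free fraction"
                    )
        return self


def cobinding_means(
    params: OccupancyParams, x4: float, rule: str = "product"
) -> dict[str, float]:
    """WT-normalised construct means under the four-state co-binding model.

    States: IRP-only (x1, efficiency y1), eIF3-only (x2, y2), co-bound
    (x4, y1*y2 or min(y1, y2)), free (remainder, efficiency 1).  Disrupting
    one site releases that factor from both its single- and co-bound
    states; the Double mutant frees everything.
    """
    x1, x2 = params.x1, params.x2
    y1, y2 = params.y1, params.y2
    x3 = 1.0 - x1 - x2 - x4
    if x3 < -1e-12:
        raise ValueError("fractions including x4 must sum to at most 1")
    x3 = max(x3, 0.0)
    y12 = y1 * y2 if rule == "product" else min(y1, y2)
    ftl = y1 * x1 + y2 * x2 + x3 + y12 * x4
    d3re = y1 * (x1 + x4) + x2 + x3      # eIF3 released from x2 and x4
    loop = y2 * (x2 + x4) + x1 + x3      # IRP released from x1 and x4
    double = x1 + x2 + x3 + x4
    return {
        "FTL": 1.0,
        "D3RE": d3re / ftl,
        "LOOP": loop / ftl,
        "DOUBLE": double / ftl,
    }


def _construct_means(p: ReporterGenParams) -> dict[str, float]:
    if p.mode == "fold_override":
        targets = p.fold_targets or DEFAULT_FOLD_TARGETS
        means = {"FTL": 1.0}
        for name, fold in targets.items():
            means[canonical_construct(name)] = float(fold)
        return means
    if p.mode == "cobinding":
        assert p.params is not None
        return cobinding_means(p.params, p.x4, p.cobinding_rule)
    assert p.params is not None
    raw = predict_raw(p.params)
    return {
        "FTL": 1.0,
        "D3RE": raw.d3re / raw.ftl,
        "LOOP": raw.loop / raw.ftl,
        "DOUBLE": raw.double / raw.ftl,
    }


def gen_reporter(p: ReporterGenParams) -> pd.DataFrame:
    """Generate a replicate-level normalized luciferase table.

    Returns a DataFrame with columns ``construct, replicate, value``.
    Replicate values are ``mean * LogNormal`` with the requested CV and
    unit expectation; the whole table is then renormalised so the sampled
    WT FTL mean is exactly 1, mirroring how reporter data are reported
    relative to the wild-type construct.
    """
    means = _construct_means(p)
    rng = np.random.default_rng(p.seed)
    sigma = float(np.sqrt(np.log1p(p.cv**2)))
    rows = []
    for construct, mean in means.items():
        if p.cv == 0:
            vals = np.full(p.n, mean)
        else:
            # mean-preserving log-normal: E[exp(N(-s^2/2, s^2))] = 1
            vals = mean * rng.lognormal(-0.5 * sigma**2, sigma, p.n)
        for i, v in enumerate(vals, start=1):
            rows.append((construct, i, float(v)))
    table = pd.DataFrame(rows, columns=["construct", "replicate", "value"])
    wt_mean = table.loc[table["construct"] == "FTL", "value"].mean()
    table["value"] /= wt_mean
    return table


def gen_timecourse(
    reaction: BindingReaction,
    noise_sd: float = 0.0,
    n_points: int = 50,
    seed: int = 2019,
    sample_times: Sequence[float] | None = None,
) -> TimeCourse:
    """Simulated bound-fraction time course with additive Gaussian noise.

    Default sampling is `n_points` evenly spaced times over the full
    reaction duration; noise is clipped to the physical [0, 1] range.
    """
    if sample_times is None:
        sample_times = np.linspace(0.0, reaction.duration, n_points)
    tc = simulate_competition(reaction, sample_times)
    if noise_sd == 0:
        return tc
    rng = np.random.default_rng(seed)
    noisy = tc.bound_fraction + rng.normal(0.0, noise_sd, len(tc.times))
    return TimeCourse(times=tc.times, bound_fraction=np.clip(noisy, 0.0, 1.0))


def gen_dose_response(
    reaction_template: BindingReaction,
    folds: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 2019,
    n_replicates: int = 1,
) -> DoseResponse:
    """End-point competition responses over a series of competitor excesses.

    Each fold-excess is simulated to the template's full duration and the
    final labeled bound fraction recorded, optionally with replicated
    additive Gaussian noise clipped to [0, 1].
    """
    folds = np.asarray(folds, dtype=float)
    if np.any(folds <= 0):
        raise ValueError("fold-excess values must be > 0")
    rng = np.random.default_rng(seed)
    all_folds, all_resp, all_rep = [], [], []
    for fold in folds:
        reaction = reaction_template.model_copy(update={"competitor_fold": float(fold)})
        tc = simulate_competition(reaction, [reaction.duration])
        clean = float(tc.bound_fraction[-1])
        for rep in range(1, n_replicates + 1):
            v = clean if noise_sd == 0 else clean + rng.normal(0.0, noise_sd)
            all_folds.append(float(fold))
            all_resp.append(float(np.clip(v, 0.0, 1.0)))
            all_rep.append(rep)
    return DoseResponse(
        folds=np.array(all_folds),
        response=np.array(all_resp),
        replicate=np.array(all_rep),
    )


def gen_utr(length: int = 120, seed: int = 11) -> str:
    """Synthetic stand-in for the FTL 5'-UTR reference sequence.

    A random RNA sequence of the requested length carrying the reference
    bases the construct recipes and variant labels expect (A15, G16, U17,
    C18, G51, G52).  It is *not* the real UTR -- only its coordinate
    landmarks are reproduced, which is all the element arithmetic needs.
    """
    if length < 91:
        raise ValueError("need at least 91 nt to span the 3RE (nt 58-90)")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGU"), size=length)
    for pos, base in {15: "A", 16: "G", 17: "U", 18: "C", 51: "G", 52: "G"}.items():
        seq[pos - 1] = base
    return "".join(seq)
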