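"""Mixed-effects models and stepwise AIC selection over metric tables.

Models are linear mixed models with mouse-level random effects, fitted by
maximum likelihood (not REML) so AIC is comparable across fixed-effect
structures. AIC = 2k - 2 logL with k counting fixed coefficients plus
random-covariance parameters plus the residual variance. Categorical
factors are treatment-coded with reference levels F (sex), explore
(state) and nonrewarded (prev_reward), so positive coefficients mean
larger responses for males / exploit / after reward; the report carries
the coding so signs can be read off.

The stepwise search follows a greedy backward descent: every child model
drops one droppable term (interactions before the main effects they
involve; main effects significant at p < 0.05 in the parent are never
dropped), the lowest-AIC child is adopted while AIC improves, with ties
broken toward fewer parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "SelectionTrace",
    "encode_factors",
    "fit_mixed_model",
    "stepwise_select",
    "standard_model_specs",
    "run_standard_models",
]

log = logging.getLogger(__name__)

CODING = {"sex": {"F": 0, "M": 1}, "state": {"explore": 0, "exploit": 1}}


@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model formula: response, fixed terms, random structure."""

    response: str
    fixed: tuple[str, ...]  # e.g. ("sex", "state", "sex:state", "reward")
    re_formula: str = "~1"  # random structure per mouse, e.g. "~state"
    groups: str = "mouse_id"

    def __post_init__(self) -> None:
        mains = {t for t in self.fixed if ":" not in t}
        for t in self.fixed:
            if ":" in t:
                missing = [p for p in t.split(":") if p not in mains]
                if missing:
                    raise ValueError(
                        f"interaction {t!r} lacks main effects {missing}"
                    )

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"

    def drop(self, term: str) -> "ModelSpec":
        if term not in self.fixed:
            raise ValueError(f"{term!r} not in model")
        return ModelSpec(
            self.response,
            tuple(t for t in self.fixed if t != term),
            self.re_formula,
            self.groups,
        )


@dataclass
class MixedModelFit:
    """Light wrapper over a statsmodels MixedLM ML fit."""

    spec: ModelSpec
    loglik: float
    aic: float
    k_params: int
    coefficients: pd.Series
    std_errors: pd.Series
    pvalues: pd.Series
    converged: bool
    re_fallback: bool = False
    _result: object = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"Mixed model (ML): {self.spec.formula}  "
            f"[re: {self.spec.re_formula} | {self.spec.groups}]",
            f"  logL = {self.loglik:.3f}  AIC = {self.aic:.3f}  "
            f"k = {self.k_params}  converged = {self.converged}"
            + ("  (random structure fell back to intercept)" if self.re_fallback else ""),
            "  coding: sex M=1 vs F=0; state exploit=1 vs explore=0; "
            "prev_reward rewarded=1",
            f"  {'term':<20s}{'beta':>12s}{'se':>12s}{'p':>12s}",
        ]
        for name in self.coefficients.index:
            lines.append(
                f"  {name:<20s}{self.coefficients[name]:>12.4f}"
                f"{self.std_errors[name]:>12.4f}{self.pvalues[name]:>12.3g}"
            )
        return "\n".join(lines)


def encode_factors(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric treatment coding for the categorical factors."""
    out = table.copy()
    for col, mapping in CODING.items():
        if col in out.columns and out[col].dtype == object:
            out[col] = out[col].map(mapping)
    if "prev_reward" in out.columns:
        out = out.rename(columns={"prev_reward": "reward"})
    return out


def _n_re_params(re_formula: str) -> int:
    k_re = 1 + (0 if re_formula.strip() in ("~1", "1") else len(
        [t for t in re_formula.replace("~", "").split("+") if t.strip() not in ("", "1")]
    ))
    return k_re * (k_re + 1) // 2


def fit_mixed_model(
    spec: ModelSpec, table: pd.DataFrame, allow_fallback: bool = True
) -> MixedModelFit:
    """ML fit of one mixed model; singular random structures fall back to
    a random intercept (flagged)."""
    data = encode_factors(table)
    needed = {v for t in spec.fixed for v in t.split(":")} | {spec.response}
    missing = sorted(needed - set(data.columns))
    if missing:
        raise ValueError(f"table lacks columns for {spec.formula}: {missing}")
    data = data.dropna(subset=[spec.response])
    if data[spec.groups].nunique() < 2:
        raise ValueError("need >= 2 grouping units (mice)")

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                spec.formula, data, groups=data[spec.groups], re_formula=re_formula
            )
            last = None
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    res = model.fit(reml=False, method=method, maxiter=500)
                except (np.linalg.LinAlgError, ValueError) as err:
                    last = err
                    continue
                if np.isfinite(res.llf) and np.all(np.isfinite(res.fe_params)):
                    return model, res
                last = np.linalg.LinAlgError(f"{method} fit diverged")
            raise last

    re_formula = spec.re_formula
    fallback = False
    try:
        model, res = _fit(re_formula)
        singular = not np.all(np.isfinite(res.bse_fe)) or np.any(
            np.linalg.eigvalsh(np.atleast_2d(res.cov_re)) < 1e-10
        )
    except (np.linalg.LinAlgError, ValueError):
        if not (allow_fallback and re_formula.strip() not in ("~1", "1")):
            raise
        singular = True
    if singular and allow_fallback and re_formula.strip() not in ("~1", "1"):
        log.warning(
            "singular random structure %s for %s; falling back to intercept",
            re_formula,
            spec.formula,
        )
        fallback = True
        re_formula = "~1"
        model, res = _fit(re_formula)
    k = model.k_fe + _n_re_params(re_formula) + 1
    fe = res.fe_params
    return MixedModelFit(
        spec=spec,
        loglik=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        k_params=int(k),
        coefficients=fe,
        std_errors=res.bse_fe,
        pvalues=res.pvalues[fe.index],
        converged=bool(res.converged),
        re_fallback=fallback,
        _result=res,
    )


def _pname(term: str) -> list[str]:
    """Candidate statsmodels coefficient names for a model term."""
    return [term, ":".join(sorted(term.split(":")))]


def _term_pvalue(fit: MixedModelFit, term: str) -> float:
    for name in _pname(term):
        if name in fit.pvalues.index:
            return float(fit.pvalues[name])
    return np.nan


def droppable_terms(spec: ModelSpec, parent: MixedModelFit, alpha: float = 0.05):
    """Terms eligible for removal: interactions always; main effects only
    when no remaining interaction involves them and they are not
    significant in the parent fit."""
    inter = [t for t in spec.fixed if ":" in t]
    mains = [t for t in spec.fixed if ":" not in t]
    out = list(inter)
    involved = {p for t in inter for p in t.split(":")}
    for m in mains:
        if m in involved:
            continue
        p = _term_pvalue(parent, m)
        if np.isnan(p) or p >= alpha:
            out.append(m)
    return out


@dataclass
class SelectionTrace:
    """Stepwise-AIC history: (spec, AIC, dropped term) per step + winner."""

    steps: list
    winner: MixedModelFit

    @property
    def winning_spec(self) -> ModelSpec:
        return self.winner.spec

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": i, "formula": s.formula, "aic": a, "dropped": d}
                for i, (s, a, d) in enumerate(self.steps)
            ]
        )


def stepwise_select(
    start: ModelSpec, table: pd.DataFrame, alpha: float = 0.05
) -> SelectionTrace:
    """Greedy backward AIC descent from the full starting model."""
    current = fit_mixed_model(start, table)
    steps = [(start, current.aic, None)]
    while True:
        children = []
        for term in droppable_terms(current.spec, current, alpha):
            try:
                child = fit_mixed_model(current.spec.drop(term), table)
            except Exception as err:  # noqa: BLE001 - skip failed child, log
                log.warning("child without %s failed: %s", term, err)
                continue
            children.append((term, child))
        if not children:
            break
        # lowest AIC, ties toward fewer parameters
        term, best = min(children, key=lambda tc: (round(tc[1].aic, 10), tc[1].k_params))
        if best.aic < current.aic - 1e-9:
            current = best
            steps.append((best.spec, best.aic, term))
        else:
            break
    return SelectionTrace(steps=steps, winner=current)


def selection_start_spec(response: str, with_reward: bool = False) -> ModelSpec:
    """Full starting model for stepwise selection: sex and state main
    effects, their interaction, and — for the reward analysis — previous
    reward with all its pairwise interactions."""
    fixed = ["sex", "state", "sex:state"]
    if with_reward:
        fixed += ["reward", "reward:sex", "reward:state"]
    re_formula = "~reward + state" if with_reward else "~state"
    return ModelSpec(response, tuple(fixed), re_formula)


def standard_model_specs() -> dict[str, ModelSpec]:
    """The winning model family fitted across the metric tables."""
    return {
        "euclidean": ModelSpec("dist_mm", ("sex", "state", "sex:state"), "~state"),
        "mahalanobis": ModelSpec("mahal", ("state",), "~state"),
        "center_distance": ModelSpec(
            "center_dist_mm", ("sex", "state", "sex:state"), "~state"
        ),
        "euclidean_reward": ModelSpec(
            "dist_mm", ("reward", "sex", "state", "sex:state"), "~reward + state"
        ),
        "mahalanobis_reward": ModelSpec(
            "mahal", ("reward", "state"), "~reward + state"
        ),
        "centroid_shift": ModelSpec("shift_mm", ("state", "sex", "state:sex"), "~1"),
        "bout_area": ModelSpec("area_mm2", ("state", "sex", "state:sex"), "~1"),
        "bout_perimeter": ModelSpec(
            "perimeter_mm", ("state", "sex", "state:sex"), "~1"
        ),
        "latency": ModelSpec("rt", ("state", "sex"), "~state"),
        "alpha_distance": ModelSpec("dist_mm", ("alpha", "sex"), "~1"),
        "n_explore_bouts": ModelSpec("n_explore", ("sex",), "~1"),
        "n_exploit_bouts": ModelSpec("n_exploit", ("sex",), "~1"),
    }


def run_standard_models(
    tables: dict[str, pd.DataFrame], skip_missing: bool = False
) -> pd.DataFrame:
    """Fit the standard winning-model family over the supplied tables.

    ``tables`` maps table names to tidy data: ``state`` (per
    mouse x session x state metrics), ``reward`` (adds prev_reward
    split), ``shifts``, ``bouts``, ``counts`` and optionally ``alpha``
    (per-mouse learning rates merged into the state table). Returns a
    long report with one row per term per model.
    """
    table_for = {
        "euclidean": "state",
        "mahalanobis": "state",
        "center_distance": "state",
        "latency": "state",
        "euclidean_reward": "reward",
        "mahalanobis_reward": "reward",
        "centroid_shift": "shifts",
        "bout_area": "bouts",
        "bout_perimeter": "bouts",
        "alpha_distance": "alpha",
        "n_explore_bouts": "counts",
        "n_exploit_bouts": "counts",
    }
    rows = []
    for name, spec in standard_model_specs().items():
        src = table_for[name]
        if src not in tables:
            if skip_missing:
                log.info("model %s skipped: table %r not supplied", name, src)
                continue
            raise KeyError(f"model {name!r} needs table {src!r}")
        table = tables[src]
        needed = {v for t in spec.fixed for v in t.split(":")} | {spec.response}
        missing = needed - set(encode_factors(table).columns)
        if missing:
            raise KeyError(
                f"model {name!r}: table {src!r} lacks columns {sorted(missing)}"
            )
        fit = fit_mixed_model(spec, table)
        for term in fit.coefficients.index:
            rows.append(
                {
                    "model": name,
                    "formula": fit.spec.formula,
                    "re_formula": fit.spec.re_formula,
                    "term": term,
                    "beta": fit.coefficients[term],
                    "se": fit.std_errors[term],
                    "p": fit.pvalues[term],
                    "converged": fit.converged,
                    "re_fallback": fit.re_fallback,
                }
            )
    return pd.DataFrame(rows)
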