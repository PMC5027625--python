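"""Mixed-model ladder, AIC comparison, and within-subject confidence intervals.

The analysis fits linear mixed models to natural-log tracking errors with a
participant random intercept, always by maximum likelihood (never REML, since
the candidate models differ in their fixed effects and REML likelihoods would
not be comparable).  Group size ("number") enters as a centered, scaled
orthogonal polynomial — linear in the baseline model, quadratic in all
others.  Candidate models drop interaction terms stepwise; the final
candidate recodes target coloration to treat orthogonally striped and
trinary (background-matching) targets as a single level, asking whether only
parallel stripes interact with the confusion effect.

Models are compared by AIC = -2 log L + 2 k, where k counts fixed-effect
coefficients plus the two variance components.  Near-ties (delta AIC < 2)
are resolved toward the model with fewer parameters, the parsimony rule used
to pick the reported model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GROUP_SIZES",
    "COLORATIONS",
    "BACKGROUNDS",
    "number_poly",
    "ModelSpec",
    "MODEL_LADDER",
    "FitResult",
    "AICTable",
    "build_design",
    "fit_mixed",
    "compare_models",
    "within_subject_ci",
]

logger = logging.getLogger("dazzletrack")

GROUP_SIZES = (1, 10, 20, 30, 40, 50, 60)
COLORATIONS = ("parallel", "orthogonal", "trinary")
BACKGROUNDS = ("plain", "trinary")


def _poly_coefs() -> np.ndarray:
    """Monomial coefficients of the orthogonal number polynomials.

    Built by QR over the seven canonical group sizes with equal weight, then
    scaled so each non-constant column has unit SD across those sizes.  The
    basis is fixed by the design (not by the data), so generator and fitter
    share it exactly.
    """
    nodes = np.asarray(GROUP_SIZES, dtype=float)
    vand = np.vander(nodes, 3, increasing=True)
    _, r = np.linalg.qr(vand)
    coefs = np.linalg.inv(r)
    vals = vand @ coefs
    coefs[:, 1:] /= vals.std(axis=0)[1:]
    # Fix signs: linear term increasing, quadratic term convex.
    if coefs[1, 1] < 0:
        coefs[:, 1] *= -1
    if coefs[2, 2] < 0:
        coefs[:, 2] *= -1
    return coefs


_POLY_COEFS = _poly_coefs()


def number_poly(group_size) -> tuple[np.ndarray, np.ndarray]:
    """Centered/scaled orthogonal linear and quadratic terms for group size."""
    n = np.asarray(group_size, dtype=float)
    vand = np.vander(np.atleast_1d(n), 3, increasing=True)
    vals = vand @ _POLY_COEFS
    return vals[:, 1], vals[:, 2]


# ---------------------------------------------------------------------------
# Candidate models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure.

    ``terms`` uses ':' for interactions; 'target', 'background' and 'number'
    main effects are named directly.  ``target_coding`` is 'three_level'
    (parallel / orthogonal / trinary) or 'merged_two_level' (parallel vs
    rest).  Every model carries a participant random intercept.
    """

    id: int
    number_form: str  # 'linear' | 'quadratic'
    terms: tuple[str, ...]
    target_coding: str = "three_level"

    def __post_init__(self) -> None:
        if self.number_form not in ("linear", "quadratic"):
            raise ValueError("number_form must be 'linear' or 'quadratic'")
        if self.target_coding not in ("three_level", "merged_two_level"):
            raise ValueError("unknown target coding")
        for t in self.terms:
            for part in t.split(":"):
                if part not in ("target", "background", "number"):
                    raise ValueError(f"unknown term component {part!r}")
            if ":" in t:
                missing = [p for p in t.split(":") if p not in self.terms]
                if missing:
                    raise ValueError(f"interaction {t} lacks main effects {missing}")


_FULL = ("target", "background", "number", "target:background",
         "target:number", "background:number", "target:background:number")

MODEL_LADDER: dict[int, ModelSpec] = {
    0: ModelSpec(0, "linear", _FULL),
    1: ModelSpec(1, "quadratic", _FULL),
    2: ModelSpec(2, "quadratic", ("target", "background", "number",
                                  "target:background", "target:number",
                                  "background:number")),
    3: ModelSpec(3, "quadratic", ("target", "background", "number",
                                  "target:number", "background:number")),
    4: ModelSpec(4, "quadratic", ("target", "background", "number",
                                  "target:number")),
    5: ModelSpec(5, "quadratic", ("target", "background", "number")),
    6: ModelSpec(6, "quadratic", ("target", "background", "number",
                                  "target:number"),
                 target_coding="merged_two_level"),
}


def build_design(data: pd.DataFrame, spec: ModelSpec,
                 ref_coloration: str = "trinary",
                 ref_background: str = "plain") -> pd.DataFrame:
    """Fixed-effect design matrix (with intercept) for one candidate model.

    Factors are treatment-coded against ``ref_coloration`` / ``ref_background``
    (any full-rank coding gives the same likelihood and AIC).  Under merged
    coding the single target contrast is parallel vs {orthogonal, trinary}.
    """
    required = {"coloration", "background", "group_size"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    col = data["coloration"].to_numpy()
    bgv = data["background"].to_numpy()
    if not set(col) <= set(COLORATIONS):
        raise ValueError(f"unknown coloration level in {set(col)}")
    if not set(bgv) <= set(BACKGROUNDS):
        raise ValueError(f"unknown background level in {set(bgv)}")

    if spec.target_coding == "merged_two_level":
        target_cols = {"target[parallel]": (col == "parallel").astype(float)}
    else:
        target_cols = {
            f"target[{lev}]": (col == lev).astype(float)
            for lev in COLORATIONS if lev != ref_coloration
        }
    bg_level = next(b for b in BACKGROUNDS if b != ref_background)
    bg = (bgv == bg_level).astype(float)
    n1, n2 = number_poly(data["group_size"].to_numpy())
    number_cols = {"n1": n1}
    if spec.number_form == "quadratic":
        number_cols["n2"] = n2

    main = {"target": target_cols,
            "background": {f"background[{bg_level}]": bg},
            "number": number_cols}

    out: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    for term in ("target", "background", "number"):
        if term in spec.terms:
            out.update(main[term])
    for term in spec.terms:
        if ":" not in term:
            continue
        parts = term.split(":")
        cols: list[tuple[str, np.ndarray]] = [("", np.ones(len(data)))]
        for part in parts:
            cols = [(f"{nm}:{cn}" if nm else cn, v * cv)
                    for nm, v in cols for cn, cv in main[part].items()]
        out.update(dict(cols))
    return pd.DataFrame(out, index=data.index)


@dataclass
class FitResult:
    """A single maximum-likelihood mixed-model fit."""

    spec: ModelSpec
    loglik: float
    k: int
    params: pd.Series
    bse: pd.Series
    re_variance: float
    resid_variance: float
    warnings: tuple[str, ...] = field(default=())

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k


def fit_mixed(data: pd.DataFrame, spec: ModelSpec, **design_kwargs) -> FitResult:
    """ML fit of log tracking error with a participant random intercept.

    ``k`` counts the fixed coefficients plus the random-intercept and
    residual variances.  Convergence/boundary warnings are attached to the
    result rather than raised.
    """
    if "log_error" not in data.columns or "participant" not in data.columns:
        raise ValueError("data must have log_error and participant columns")
    if data["participant"].nunique() < 2:
        raise ValueError("mixed model requires at least 2 participants")
    exog = build_design(data, spec, **design_kwargs)
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(data["log_error"].to_numpy(), exog,
                           groups=data["participant"].to_numpy())
        res = model.fit(reml=False)
    notes = tuple(str(w.message) for w in caught)
    k = exog.shape[1] + 2
    return FitResult(
        spec=spec,
        loglik=float(res.llf),
        k=k,
        params=pd.Series(np.asarray(res.fe_params), index=exog.columns),
        bse=pd.Series(np.asarray(res.bse_fe), index=exog.columns),
        re_variance=float(np.squeeze(res.cov_re)),
        resid_variance=float(res.scale),
        warnings=notes,
    )


@dataclass
class AICTable:
    """Ordered model comparison.

    ``table`` is sorted by AIC and carries a delta_aic column; rows within
    delta AIC < 2 of the best are annotated "prefer fewer terms".
    """

    fits: dict[int, FitResult]
    table: pd.DataFrame

    @property
    def best_aic(self) -> int:
        """Model id with the strictly minimal AIC."""
        return int(self.table.iloc[0]["model_id"])

    def select(self, tie_delta: float = 2.0) -> int:
        """Paper-style selection: among near-ties, prefer fewest parameters."""
        near = self.table[self.table["delta_aic"] < tie_delta]
        near = near.sort_values(["k", "aic"], kind="stable")
        return int(near.iloc[0]["model_id"])


def compare_models(data: pd.DataFrame,
                   specs: dict[int, ModelSpec] | None = None) -> AICTable:
    """Fit every candidate model on the same rows and rank by AIC."""
    specs = MODEL_LADDER if specs is None else specs
    fits: dict[int, FitResult] = {}
    rows = []
    for mid, spec in specs.items():
        try:
            fit = fit_mixed(data, spec)
        except Exception as exc:  # noqa: BLE001 - excluded with logged reason
            logger.warning("model %s excluded from comparison: %s", mid, exc)
            continue
        fits[mid] = fit
        rows.append({"model_id": mid,
                     "terms": " + ".join(spec.terms),
                     "number_form": spec.number_form,
                     "target_coding": spec.target_coding,
                     "k": fit.k,
                     "loglik": fit.loglik,
                     "aic": fit.aic})
    if not rows:
        raise ValueError("no model could be fitted")
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["note"] = np.where(table["delta_aic"] < 2.0, "prefer fewer terms", "")
    return AICTable(fits=fits, table=table)


def within_subject_ci(data: pd.DataFrame, value: str = "log_error",
                      level: float = 0.95) -> pd.DataFrame:
    """Cousineau-Morey within-subject confidence intervals per design cell.

    Each participant's cell means are centered on the grand mean (removing
    between-participant offsets); the per-cell SD of the centered means gives
    the CI, inflated by the Morey factor sqrt(C / (C - 1)) for C cells.
    """
    cells = ["coloration", "background", "group_size"]
    part_means = (data.groupby(["participant"] + cells, observed=True)[value]
                  .mean().unstack(cells))
    if part_means.isna().any().any():
        raise ValueError("every participant must contribute to every cell")
    n_part = part_means.shape[0]
    if n_part < 2:
        raise ValueError("within-subject CIs require at least 2 participants")
    n_cells = part_means.shape[1]
    centered = part_means.sub(part_means.mean(axis=1), axis=0) + part_means.to_numpy().mean()
    morey = np.sqrt(n_cells / (n_cells - 1.0))
    tcrit = stats.t.ppf(0.5 + level / 2.0, n_part - 1)
    half = centered.std(axis=0, ddof=1) / np.sqrt(n_part) * morey * tcrit
    out = pd.DataFrame({
        "mean": part_means.mean(axis=0),
        "ci_half_width": half,
        "n_participants": n_part,
    }).reset_index()
    return out.sort_values(cells, kind="stable").reset_index(drop=True)
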