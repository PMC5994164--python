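"""PEM trait regression: AICc selection, leave-one-out validation, prediction.

The predictive model regresses the log10 response (resting metabolic rate in
mL O2 h^-1 g^-0.67, or periosteal bone apposition rate in um/day) on an
intercept, a chosen subset of PEM eigenvectors, and the log10 predictor
(primary osteon density, a fraction of cortical bone area).  Model choice is
by Gaussian AICc,

    AICc = n * ln(RSS / n) + 2k + 2k(k + 1) / (n - k - 1),

with k counting the intercept, all slopes and the residual variance.
Eigenvectors enter by forward selection in order of decreasing singular
value, stopping at the first candidate that fails to lower AICc; the PEM
steepness parameter ``a`` can be fixed or chosen on a grid by the same
criterion.  Fossil tips are predicted with 95% intervals (prediction
intervals by default — they describe a new observation, matching how the
fossil estimates are plotted — or confidence-of-mean intervals on request).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import pem as pem_mod
from .trees import PhyloTree

ROLE_TRAINING = "training"
ROLE_TARGET = "target"

#: AICc improvements smaller than this count as ties; the smaller model wins.
AICC_TIE = 1e-9

#: default steepness grid: 0, 0.01, ..., 1
STEEPNESS_GRID = tuple(np.round(np.linspace(0.0, 1.0, 101), 2))


@dataclass
class TraitTable:
    """Per-species predictor/response table with training/target roles.

    ``data`` columns: ``species``, ``density`` (primary osteon density,
    fraction in (0, 1) on the natural scale), ``response`` (positive, NaN
    for targets), ``role`` (``training`` or ``target``).  ``scale`` records
    whether values are natural or log10.
    """

    data: pd.DataFrame
    scale: str = "natural"

    def __post_init__(self):
        required = {"species", "density", "response", "role"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        bad_roles = set(self.data["role"]) - {ROLE_TRAINING, ROLE_TARGET}
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        dup = self.data["species"][self.data["species"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate species: {sorted(set(dup))}")
        targets = self.data[self.data["role"] == ROLE_TARGET]
        if targets["response"].notna().any():
            raise ValueError("target species must not carry a response value")
        training = self.data[self.data["role"] == ROLE_TRAINING]
        if training["response"].isna().any():
            bad = training.loc[training["response"].isna(), "species"].tolist()
            raise ValueError(f"training species without response: {bad}")

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        df = pd.read_csv(path)
        return cls(df[["species", "density", "response", "role"]].copy())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def training(self) -> pd.DataFrame:
        return self.data[self.data["role"] == ROLE_TRAINING].reset_index(drop=True)

    @property
    def targets(self) -> pd.DataFrame:
        return self.data[self.data["role"] == ROLE_TARGET].reset_index(drop=True)

    def training_labels(self) -> list[str]:
        return self.training["species"].tolist()

    def target_labels(self) -> list[str]:
        return self.targets["species"].tolist()

    def drop_species(self, label: str) -> "TraitTable":
        kept = self.data[self.data["species"] != label].reset_index(drop=True)
        return TraitTable(kept, scale=self.scale)

    def as_target(self, label: str) -> "TraitTable":
        """Demote one training species to target (response withheld)."""
        df = self.data.copy()
        mask = df["species"] == label
        if not mask.any():
            raise KeyError(label)
        df.loc[mask, "role"] = ROLE_TARGET
        df.loc[mask, "response"] = np.nan
        return TraitTable(df.reset_index(drop=True), scale=self.scale)


def log_transform(table: TraitTable) -> TraitTable:
    """Base-10 logarithm of predictor and response; roles preserved.

    Both variables span orders of magnitude across amniotes, so the model is
    fit on the log10 scale throughout.
    """
    if table.scale == "log10":
        return table
    df = table.data.copy()
    bad = df[(df["density"] <= 0) | (df["response"].notna() & (df["response"] <= 0))]
    if len(bad):
        raise ValueError(
            f"non-positive value(s) for species {bad['species'].tolist()}; "
            "log transform requires positive predictor and response"
        )
    df["density"] = np.log10(df["density"].astype(float))
    df["response"] = np.log10(df["response"].astype(float))
    return TraitTable(df, scale="log10")


def back_transform(values):
    """Inverse of :func:`log_transform` (plain base-10 exponentiation)."""
    return np.power(10.0, np.asarray(values, dtype=float))


def gaussian_aicc(n: int, rss: float, n_mean_params: int) -> float:
    """Gaussian AICc; ``k = n_mean_params + 1`` (residual variance counted).

    Returns ``inf`` when the small-sample correction denominator is not
    positive, so such candidates are rejected rather than raising.  RSS is
    floored at a tiny positive value to keep noiseless fits finite.
    """
    k = n_mean_params + 1
    if n - k - 1 <= 0:
        return math.inf
    rss = max(float(rss), 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelFit:
    """A fitted PEM regression with everything needed to predict new tips."""

    a: float
    psi: float
    selected: tuple[int, ...]  # eigenvector column indices, singular-value order
    coef: np.ndarray  # [intercept, gamma_1.., beta1]
    coef_names: list[str]
    n: int
    rss: float
    sigma2: float  # unbiased residual variance RSS / (n - p)
    aicc: float
    xtx_inv: np.ndarray
    basis: pem_mod.PEMBasis
    fitted: np.ndarray
    residuals: np.ndarray
    species: list[str]

    @property
    def n_mean_params(self) -> int:
        return len(self.coef)

    @property
    def df_resid(self) -> int:
        return self.n - self.n_mean_params

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def slope_density(self) -> float:
        return float(self.coef[-1])

    def design_row(self, scores: np.ndarray, log_density: float) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return np.concatenate(([1.0], s[list(self.selected)], [log_density]))

    def report(self) -> dict:
        return {
            "a": self.a,
            "psi": self.psi,
            "selected_eigenvectors": [int(i) for i in self.selected],
            "coefficients": {
                name: float(c) for name, c in zip(self.coef_names, self.coef)
            },
            "n_training": self.n,
            "rss": float(self.rss),
            "sigma2": float(self.sigma2),
            "aicc": float(self.aicc),
        }


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with explicit rank check; None when the design is singular."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        return None
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    return coef, resid, rss


def fit_pem_regression(
    basis: pem_mod.PEMBasis,
    table: TraitTable,
    selection: str = "forward",
) -> ModelFit:
    """OLS of log response on [intercept, selected eigenvectors, log density].

    ``selection``:
      * ``"forward"`` — eigenvectors tried in singular-value order; each is
        kept only if it lowers AICc by more than the tie tolerance; the scan
        stops at the first rejection.
      * ``"all"`` — as many leading eigenvectors as the small-sample AICc
        denominator allows.
      * ``"none"`` — log density and intercept only.
    """
    if selection not in ("forward", "all", "none"):
        raise ValueError(f"unknown selection strategy {selection!r}")
    table = log_transform(table)
    train = table.training
    if len(train) < 4:
        raise ValueError(f"need >= 4 training species, got {len(train)}")
    order = {lab: i for i, lab in enumerate(basis.tip_labels)}
    missing = [s for s in train["species"] if s not in order]
    if missing:
        raise ValueError(f"training species not in basis: {missing}")
    rows = [order[s] for s in train["species"]]
    U = basis.U[rows]
    y = train["response"].to_numpy(dtype=float)
    x = train["density"].to_numpy(dtype=float)
    n = len(y)

    def design(sel: tuple[int, ...]) -> np.ndarray:
        return np.column_stack([np.ones(n), U[:, list(sel)], x])

    # RSS below numerical zero (relative to the response's total variation) is
    # treated as exactly zero, so noiseless fits compare by parameter count
    # alone instead of by round-off in the residual
    tss = float(np.sum((y - y.mean()) ** 2))
    rss_floor = 1e-16 * max(tss, 1.0)

    def evaluate(sel: tuple[int, ...]):
        X = design(sel)
        fit = _ols(X, y)
        if fit is None:
            return None
        coef, resid, rss = fit
        aicc = gaussian_aicc(n, max(rss, rss_floor), X.shape[1])
        if not math.isfinite(aicc):
            return None
        return sel, coef, resid, rss, aicc

    base = evaluate(())
    if base is None:
        raise ValueError("base model (intercept + log density) could not be fit")

    if selection == "none":
        best = base
    elif selection == "all":
        best = base
        for j in range(basis.rank):
            cand = evaluate(best[0] + (j,))
            if cand is None:
                break
            best = cand
    else:  # forward
        best = base
        for j in range(basis.rank):
            cand = evaluate(best[0] + (j,))
            if cand is None:
                break
            if cand[4] < best[4] - AICC_TIE:
                best = cand
            else:
                break

    sel, coef, resid, rss, aicc = best
    X = design(sel)
    p = X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss / (n - p) if n > p else 0.0
    names = ["intercept"] + [f"V{j + 1}" for j in sel] + ["log10_density"]
    return ModelFit(
        a=basis.weights.a,
        psi=basis.weights.psi,
        selected=sel,
        coef=coef,
        coef_names=names,
        n=n,
        rss=rss,
        sigma2=sigma2,
        aicc=aicc,
        xtx_inv=xtx_inv,
        basis=basis,
        fitted=X @ coef,
        residuals=resid,
        species=train["species"].tolist(),
    )


def fit_trait_model(
    tree: PhyloTree,
    table: TraitTable,
    steepness: float | str = "grid",
    selection: str = "forward",
    psi: float = 1.0,
) -> tuple[ModelFit, dict[str, np.ndarray]]:
    """Fit the full model on an analysis tree carrying training + target tips.

    ``steepness`` is either a fixed value in [0, 1] or ``"grid"``, which
    scans a = 0, 0.01, ..., 1 and keeps the AICc-best selected model (ties
    resolved towards fewer parameters, then smaller a).  Returns the fit and
    the PEM scores of every target tip.
    """
    table = log_transform(table)
    if len(table.training) < 4:
        raise ValueError(f"need >= 4 training species, got {len(table.training)}")
    training = table.training_labels()
    targets = table.target_labels()
    tips = set(tree.tip_labels())
    missing = sorted(set(training + targets) - tips)
    if missing:
        raise ValueError(f"species absent from tree: {missing}")

    if isinstance(steepness, str):
        if steepness != "grid":
            raise ValueError(f"steepness must be a float or 'grid', got {steepness!r}")
        grid = STEEPNESS_GRID
    else:
        grid = (float(steepness),)

    best_fit = None
    best_scores = None
    for a in grid:
        basis, scores = pem_mod.training_basis_with_targets(
            tree, training, targets, a=a, psi=psi
        )
        try:
            fit = fit_pem_regression(basis, table, selection=selection)
        except ValueError:
            continue
        if best_fit is None:
            best_fit, best_scores = fit, scores
            continue
        if fit.aicc < best_fit.aicc - AICC_TIE or (
            abs(fit.aicc - best_fit.aicc) <= AICC_TIE
            and fit.n_mean_params < best_fit.n_mean_params
        ):
            best_fit, best_scores = fit, scores
    if best_fit is None:
        raise ValueError("no steepness value produced a fittable model")
    return best_fit, best_scores


@dataclass
class PredictionResult:
    """Point estimate with 95% bounds, on the log10 scale and in natural units."""

    species: str
    log_point: float
    log_lower: float
    log_upper: float
    interval: str = "prediction"
    level: float = 0.95

    @property
    def point(self) -> float:
        return float(back_transform(self.log_point))

    @property
    def lower(self) -> float:
        return float(back_transform(self.log_lower))

    @property
    def upper(self) -> float:
        return float(back_transform(self.log_upper))

    def as_dict(self) -> dict:
        return {
            "species": self.species,
            "log_point": self.log_point,
            "log_lower": self.log_lower,
            "log_upper": self.log_upper,
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "interval": self.interval,
            "level": self.level,
        }


def predict_fossil(
    fit: ModelFit,
    scores: np.ndarray,
    log_density: float,
    species: str = "",
    interval: str = "prediction",
    level: float = 0.95,
) -> PredictionResult:
    """Predict one target tip from its PEM scores and log10 density.

    ``interval="prediction"`` adds the residual variance (uncertainty of a
    new observation); ``"confidence"`` covers the conditional mean only.
    Natural-scale values are plain base-10 exponentiation of the three
    log-scale numbers.
    """
    if interval not in ("prediction", "confidence"):
        raise ValueError(f"unknown interval type {interval!r}")
    df = fit.df_resid
    if df <= 0:
        raise ValueError("no residual degrees of freedom for an interval")
    h = fit.design_row(scores, log_density)
    point = float(h @ fit.coef)
    leverage = float(h @ fit.xtx_inv @ h)
    extra = 1.0 if interval == "prediction" else 0.0
    se = math.sqrt(fit.sigma2 * (extra + leverage))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df))
    return PredictionResult(
        species=species,
        log_point=point,
        log_lower=point - tcrit * se,
        log_upper=point + tcrit * se,
        interval=interval,
        level=level,
    )


def predict_targets(
    fit: ModelFit,
    scores: dict[str, np.ndarray],
    table: TraitTable,
    interval: str = "prediction",
    level: float = 0.95,
) -> list[PredictionResult]:
    """Predict every target species of a trait table."""
    table = log_transform(table)
    targets = table.targets.set_index("species")
    out = []
    for lab in table.target_labels():
        out.append(
            predict_fossil(
                fit,
                scores[lab],
                float(targets.loc[lab, "density"]),
                species=lab,
                interval=interval,
                level=level,
            )
        )
    return out


@dataclass
class LoocvResult:
    """Per-fold held-out predictions (log10 scale) and the PRESS statistic."""

    table: pd.DataFrame  # species, observed, predicted, lower, upper, ok
    press: float
    n_folds_completed: int

    @property
    def failed_folds(self) -> list[str]:
        return self.table.loc[~self.table["ok"], "species"].tolist()


def loocv(
    tree: PhyloTree,
    table: TraitTable,
    steepness: float | str = "grid",
    selection: str = "forward",
    psi: float = 1.0,
    interval: str = "prediction",
) -> LoocvResult:
    """Leave-one-out cross-validation of the full fitting procedure.

    Each fold demotes one training species to target, repeats basis
    construction, steepness choice and eigenvector selection on the
    remaining species, and predicts the held-out response.  PRESS is the sum
    of squared log10 errors over completed folds; a fold whose refit fails
    is flagged rather than raised.
    """
    table = log_transform(table)
    train = table.training
    if len(train) < 5:
        raise ValueError(f"LOOCV needs >= 5 training species, got {len(train)}")
    rows = []
    press = 0.0
    completed = 0
    for lab in sorted(train["species"]):
        observed = float(train.set_index("species").loc[lab, "response"])
        try:
            fold_table = table.as_target(lab)
            fit, scores = fit_trait_model(
                tree, fold_table, steepness=steepness, selection=selection, psi=psi
            )
            res = predict_fossil(
                fit,
                scores[lab],
                float(fold_table.targets.set_index("species").loc[lab, "density"]),
                species=lab,
                interval=interval,
            )
            rows.append(
                {
                    "species": lab,
                    "observed": observed,
                    "predicted": res.log_point,
                    "lower": res.log_lower,
                    "upper": res.log_upper,
                    "ok": True,
                }
            )
            press += (observed - res.log_point) ** 2
            completed += 1
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            rows.append(
                {
                    "species": lab,
                    "observed": observed,
                    "predicted": np.nan,
                    "lower": np.nan,
                    "upper": np.nan,
                    "ok": False,
                }
            )
    df = pd.DataFrame(rows)
    return LoocvResult(table=df, press=press, n_folds_completed=completed)
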