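"""Partial least squares regression for CoMFA field matrices.

The field matrix has thousands of heavily collinear columns and a couple of
dozen rows, so an ordinary regression is hopeless; PLS extracts a small
number of latent components that maximize covariance with activity.  This
module implements:

* the CoMFA column pipeline: minimum-sigma filtering plus block scaling
  (each field block is centered and divided by its pooled standard
  deviation, so steric and electrostatic columns enter with equal weight),
* PLS1 via the NIPALS algorithm (deterministic, no randomness),
* leave-one-out cross-validation with per-fold refiltering/rescaling,
  yielding q2 per component count and the optimal component number,
* the standard CoMFA model statistics: r2, SEE, external r2pred and the
  per-field fractional contributions.

Conventions reproduced here (each also exposed where there is a choice):
SEE = sqrt(SSres / (n - c - 1)) with c latent components; r2pred is the
squared Pearson correlation between predicted and observed test activities,
with the PRESS/SD variant reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ColumnFilterError, FitError, SchemaError
from .fields import FieldMatrix

__all__ = [
    "QSARDataset",
    "ScaledDesign",
    "PLSModel",
    "Q2Result",
    "MetricsReport",
    "filter_and_scale",
    "fit_pls",
    "loo_q2",
    "predict",
    "model_metrics",
    "training_r2",
    "standard_error_of_estimate",
    "r2pred_pearson",
    "r2pred_press",
]


@dataclass
class QSARDataset:
    """Row-aligned field matrix + activities with train/test roles."""

    X: FieldMatrix
    y: np.ndarray  # pLC50, -log10 mol/L
    roles: list[str]  # "train" / "test" per compound

    def __post_init__(self) -> None:
        n = len(self.X.compound_ids)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (n,) or len(self.roles) != n:
            raise SchemaError("X, y and roles must have one entry per compound")
        if not np.all(np.isfinite(self.y)):
            raise SchemaError("activities must be finite")

    def subset(self, role: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        idx = [i for i, r in enumerate(self.roles) if r == role]
        ids = [self.X.compound_ids[i] for i in idx]
        return self.X.values[idx], self.y[idx], ids


# ---------------------------------------------------------------------------
# column filtering and scaling


@dataclass
class ScaledDesign:
    """Frozen column filter + scaling learned from a training matrix.

    ``transform`` maps raw field-matrix rows (full column set) into the
    filtered, centered, block-scaled design space the model was fitted in.
    """

    kept: np.ndarray  # indices into the original columns
    col_means: np.ndarray  # per kept column
    col_scale: np.ndarray  # per kept column (its block's pooled sd)
    blocks: np.ndarray  # block label per kept column
    n_original_columns: int
    min_sigma: float
    scaling: str
    X: np.ndarray = field(repr=False)  # scaled training design

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
        if X_raw.shape[1] != self.n_original_columns:
            raise SchemaError(
                f"expected {self.n_original_columns} columns, got {X_raw.shape[1]}"
            )
        # C-contiguous so BLAS summation order (hence bitwise results) matches
        # the training design exactly
        return np.ascontiguousarray(
            (X_raw[:, self.kept] - self.col_means) / self.col_scale
        )


def _column_blocks(X) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, FieldMatrix):
        return X.values, X.column_kinds
    X = np.asarray(X, dtype=float)
    return X, np.array(["all"] * X.shape[1])


def filter_and_scale(
    X,
    min_sigma: float = 2.0,
    scaling: str = "comfa_std",
    blocks: np.ndarray | None = None,
) -> ScaledDesign:
    """Drop low-variation columns and apply CoMFA-standard block scaling.

    ``X`` may be a :class:`FieldMatrix` (block labels inferred) or a plain
    array (single block unless ``blocks`` is given).  Columns with standard
    deviation below ``min_sigma`` are dropped.  Under ``"comfa_std"`` each
    kept column is centered and divided by its block's pooled standard
    deviation (sqrt of the mean column variance), which equalizes the total
    variance weight of the blocks.  ``"autoscale"`` divides each column by
    its own sd; ``"none"`` only centers.
    """
    values, inferred = _column_blocks(X)
    blk = inferred if blocks is None else np.asarray(blocks)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ColumnFilterError("need at least two rows to filter and scale")
    sd = values.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd >= min_sigma)
    if kept.size == 0:
        raise ColumnFilterError(
            f"no column has sd >= {min_sigma}; lower min_sigma"
        )
    sub = values[:, kept]
    means = sub.mean(axis=0)
    centered = sub - means
    var = centered.var(axis=0, ddof=1)
    kept_blocks = blk[kept]
    scale = np.ones(kept.size)
    if scaling == "comfa_std":
        for b in np.unique(kept_blocks):
            mask = kept_blocks == b
            pooled = np.sqrt(var[mask].mean())
            if pooled > 0:
                scale[mask] = pooled
    elif scaling == "autoscale":
        scale = np.where(np.sqrt(var) > 0, np.sqrt(var), 1.0)
    elif scaling == "none":
        pass
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return ScaledDesign(
        kept=kept,
        col_means=means,
        col_scale=scale,
        blocks=kept_blocks,
        n_original_columns=values.shape[1],
        min_sigma=min_sigma,
        scaling=scaling,
        X=np.ascontiguousarray(centered / scale),
    )


# ---------------------------------------------------------------------------
# NIPALS PLS1


def _nipals_pls1(
    Xc: np.ndarray, yc: np.ndarray, n_components: int, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """NIPALS on centered data; returns (W, P, q, achieved components)."""
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    Xd = Xc.copy()
    yd = yc.copy()
    achieved = 0
    for k in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < tol:
            break
        W[:, k] = w
        P[:, k] = Xd.T @ t / tt
        q[k] = (yd @ t) / tt
        Xd -= np.outer(t, P[:, k])
        yd -= q[k] * t
        achieved = k + 1
    return W[:, :achieved], P[:, :achieved], q[:achieved], achieved


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, c: int) -> np.ndarray:
    if c == 0:
        return np.zeros(W.shape[0])
    Wc, Pc, qc = W[:, :c], P[:, :c], q[:c]
    return Wc @ np.linalg.solve(Pc.T @ Wc, qc)


@dataclass
class PLSModel:
    """A fitted PLS1 model over a frozen column filter/scaling."""

    design: ScaledDesign
    n_components: int
    x_weights: np.ndarray = field(repr=False)
    x_loadings: np.ndarray = field(repr=False)
    y_loadings: np.ndarray = field(repr=False)
    coefficients: np.ndarray = field(repr=False)  # scaled-design space
    intercept: float
    fitted: np.ndarray = field(repr=False)
    r2: float
    see: float
    rank_exhausted: bool = False
    q2: float | None = None

    @property
    def contributions(self) -> dict[str, float]:
        """Fractional field contributions: sum of |coef|*sd per block, normalized."""
        sd = self.design.X.std(axis=0, ddof=1)
        weight = np.abs(self.coefficients) * sd
        out: dict[str, float] = {}
        for b in np.unique(self.design.blocks):
            out[str(b)] = float(weight[self.design.blocks == b].sum())
        total = sum(out.values())
        if total > 0:
            out = {k: v / total for k, v in out.items()}
        return out

    def to_json(self) -> str:
        d = {
            "n_components": self.n_components,
            "intercept": self.intercept,
            "r2": self.r2,
            "see": self.see,
            "q2": self.q2,
            "rank_exhausted": self.rank_exhausted,
            "coefficients": self.coefficients.tolist(),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "fitted": self.fitted.tolist(),
            "design": {
                "kept": self.design.kept.tolist(),
                "col_means": self.design.col_means.tolist(),
                "col_scale": self.design.col_scale.tolist(),
                "blocks": self.design.blocks.tolist(),
                "n_original_columns": self.design.n_original_columns,
                "min_sigma": self.design.min_sigma,
                "scaling": self.design.scaling,
                "X": self.design.X.tolist(),
            },
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        ds = d["design"]
        design = ScaledDesign(
            kept=np.array(ds["kept"], dtype=int),
            col_means=np.array(ds["col_means"]),
            col_scale=np.array(ds["col_scale"]),
            blocks=np.array(ds["blocks"]),
            n_original_columns=int(ds["n_original_columns"]),
            min_sigma=float(ds["min_sigma"]),
            scaling=ds["scaling"],
            X=np.array(ds["X"]),
        )
        return cls(
            design=design,
            n_components=int(d["n_components"]),
            x_weights=np.array(d["x_weights"]),
            x_loadings=np.array(d["x_loadings"]),
            y_loadings=np.array(d["y_loadings"]),
            coefficients=np.array(d["coefficients"]),
            intercept=float(d["intercept"]),
            fitted=np.array(d["fitted"]),
            r2=float(d["r2"]),
            see=float(d["see"]),
            rank_exhausted=bool(d["rank_exhausted"]),
            q2=d["q2"],
        )


def fit_pls(design: ScaledDesign | np.ndarray, y, n_components: int) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent variables.

    ``design`` is the output of :func:`filter_and_scale`; a plain (already
    preprocessed) matrix is wrapped in an identity design.  Deterministic:
    NIPALS involves no randomness, so refitting reproduces coefficients
    bitwise.
    """
    if not isinstance(design, ScaledDesign):
        X = np.asarray(design, dtype=float)
        means = X.mean(axis=0)
        design = ScaledDesign(
            kept=np.arange(X.shape[1]),
            col_means=means,
            col_scale=np.ones(X.shape[1]),
            blocks=np.array(["all"] * X.shape[1]),
            n_original_columns=X.shape[1],
            min_sigma=0.0,
            scaling="none",
            X=X - means,
        )
    y = np.asarray(y, dtype=float)
    n, p = design.X.shape
    if y.shape != (n,):
        raise SchemaError("y length must match the number of rows")
    if not 1 <= n_components <= min(n - 1, p):
        raise FitError(
            f"n_components must be in [1, {min(n - 1, p)}] for a {n}x{p} design"
        )
    y_mean = float(y.mean())
    W, P, q, achieved = _nipals_pls1(design.X, y - y_mean, n_components)
    coef = _coefficients(W, P, q, achieved)
    fitted = y_mean + design.X @ coef
    res = y - fitted
    sst = float(((y - y_mean) ** 2).sum())
    r2 = 1.0 - float((res**2).sum()) / sst if sst > 0 else float("nan")
    see = standard_error_of_estimate(res, achieved)
    return PLSModel(
        design=design,
        n_components=achieved,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
        intercept=y_mean,
        fitted=fitted,
        r2=r2,
        see=see,
        rank_exhausted=achieved < n_components,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict activities for raw field-matrix rows (full column set)."""
    if isinstance(X_new, FieldMatrix):
        X_new = X_new.values
    Xs = model.design.transform(X_new)
    return model.intercept + Xs @ model.coefficients


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


@dataclass
class Q2Result:
    """q2 per component count (index 0 = one component) and the optimum."""

    q2: np.ndarray
    press: np.ndarray
    optimum: int  # component count with the highest q2 (ties -> fewer)
    fold_mean: str
    degenerate: bool = False

    @property
    def best_q2(self) -> float:
        return float(self.q2[self.optimum - 1])


def loo_q2(
    X,
    y,
    max_components: int = 10,
    min_sigma: float = 2.0,
    scaling: str = "comfa_std",
    fold_mean: str = "loo",
    blocks: np.ndarray | None = None,
) -> Q2Result:
    """Leave-one-out q2 for 1..max_components latent variables.

    Every fold repeats the full preprocessing (minimum-sigma filter and
    block scaling) on the retained rows before fitting, so the held-out
    prediction is honest.  ``fold_mean="loo"`` uses the per-fold training
    mean in the q2 denominator; ``"fixed"`` uses the overall mean.
    """
    values, blk = _column_blocks(X)
    if blocks is not None:
        blk = np.asarray(blocks)
    y = np.asarray(y, dtype=float)
    n = values.shape[0]
    if n < 3:
        raise FitError("need at least 3 rows for leave-one-out validation")
    if fold_mean not in ("loo", "fixed"):
        raise ValueError(f"unknown fold_mean {fold_mean!r}")
    max_c = min(max_components, n - 2)
    preds = np.full((n, max_c), np.nan)
    denom_terms = np.empty(n)
    for i in range(n):
        rows = np.arange(n) != i
        Xi, yi = values[rows], y[rows]
        if np.allclose(Xi.std(axis=0, ddof=1), 0.0):
            return Q2Result(
                q2=np.full(max_c, np.nan),
                press=np.full(max_c, np.nan),
                optimum=1,
                fold_mean=fold_mean,
                degenerate=True,
            )
        design = filter_and_scale(Xi, min_sigma=min_sigma, scaling=scaling, blocks=blk)
        ym = float(yi.mean())
        W, P, q, achieved = _nipals_pls1(design.X, yi - ym, max_c)
        xs = design.transform(values[i : i + 1])[0]
        for c in range(1, max_c + 1):
            coef = _coefficients(W, P, q, min(c, achieved))
            preds[i, c - 1] = ym + xs @ coef
        denom_terms[i] = (y[i] - ym) ** 2 if fold_mean == "loo" else (y[i] - y.mean()) ** 2
    denom = float(denom_terms.sum())
    press = ((y[:, None] - preds) ** 2).sum(axis=0)
    if denom <= 0:
        return Q2Result(
            q2=np.full(max_c, np.nan),
            press=press,
            optimum=1,
            fold_mean=fold_mean,
            degenerate=True,
        )
    q2 = 1.0 - press / denom
    optimum = int(np.argmax(q2)) + 1  # argmax returns the first (smallest) index
    return Q2Result(q2=q2, press=press, optimum=optimum, fold_mean=fold_mean)


# ---------------------------------------------------------------------------
# model statistics


def training_r2(y, y_fitted) -> float:
    """Coefficient of determination 1 - SSres/SStot."""
    y = np.asarray(y, dtype=float)
    y_fitted = np.asarray(y_fitted, dtype=float)
    res = y - y_fitted
    sst = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (res**2).sum() / sst)


def standard_error_of_estimate(residuals, n_components: int) -> float:
    """SEE = sqrt(SSres / (n - c - 1)) in activity units."""
    res = np.asarray(residuals, dtype=float)
    dof = res.size - n_components - 1
    if dof <= 0:
        return float("nan")
    return float(np.sqrt((res**2).sum() / dof))


def r2pred_pearson(y_test, y_pred) -> float:
    """Squared Pearson correlation between predicted and observed test values."""
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    r = np.corrcoef(y_test, y_pred)[0, 1]
    return float(r**2)


def r2pred_press(y_test, y_pred, y_train_mean: float) -> float:
    """External PRESS/SD form: 1 - sum((obs-pred)^2)/sum((obs-train mean)^2)."""
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    sd = ((y_test - y_train_mean) ** 2).sum()
    return float(1.0 - ((y_test - y_pred) ** 2).sum() / sd)


@dataclass
class MetricsReport:
    n_train: int
    n_test: int
    n_components: int
    r2: float
    see: float
    q2: float | None
    r2pred: float | None  # squared Pearson correlation on the test set
    r2pred_press: float | None
    contributions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_components": self.n_components,
            "r2": self.r2,
            "see": self.see,
            "q2": self.q2,
            "r2pred": self.r2pred,
            "r2pred_press": self.r2pred_press,
            "contributions": self.contributions,
        }


def model_metrics(
    model: PLSModel,
    y_train,
    X_test=None,
    y_test=None,
) -> MetricsReport:
    """Assemble the standard CoMFA statistics for a fitted model.

    The external predictivity r2pred is the squared Pearson correlation
    between predicted and experimental test activities; the PRESS/SD
    alternative is reported alongside under ``r2pred_press``.  Field
    contributions are normalized sums of |coefficient| * column sd per block.
    """
    y_train = np.asarray(y_train, dtype=float)
    r2 = training_r2(y_train, model.fitted)
    see = standard_error_of_estimate(y_train - model.fitted, model.n_components)
    r2p = r2p_press = None
    n_test = 0
    if X_test is not None and y_test is not None and len(np.atleast_1d(y_test)) > 0:
        y_test = np.asarray(y_test, dtype=float)
        n_test = y_test.size
        y_hat = predict(model, X_test)
        r2p = r2pred_pearson(y_test, y_hat)
        r2p_press = r2pred_press(y_test, y_hat, float(y_train.mean()))
    return MetricsReport(
        n_train=y_train.size,
        n_test=n_test,
        n_components=model.n_components,
        r2=r2,
        see=see,
        q2=model.q2,
        r2pred=r2p,
        r2pred_press=r2p_press,
        contributions=model.contributions,
    )
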