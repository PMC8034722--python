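"""Generalized linear models across horizontally partitioned study nodes.

The defining property of the federated fit is *pooled equivalence*: because
iteratively reweighted least squares (IRLS) only ever touches the data
through the weighted cross-products ``X'WX`` and ``X'Wz``, and both are sums
over rows, each node can compute its own share and the client can add the
shares. The update

    beta <- (sum_k X_k' W_k X_k)^(-1) (sum_k X_k' W_k z_k)

is algebraically identical to the pooled single-machine update, so the
federated estimates, standard errors and deviance equal those of an analysis
run directly on the concatenated raw data — while only ``p``-dimensional
aggregates ever leave a node.

Supported families (canonical links): gaussian/identity, binomial/logit,
poisson/log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy

from .disclosure import check_model_validity
from .federation import ClientSession, GuardContext, server_op


class GLMError(Exception):
    pass


class NonIdentifiableError(GLMError):
    """Singular summed information: the model cannot be identified."""


class FederatedBlockedError(GLMError):
    """A node's disclosure policy blocked the fit; carries its messages."""

    def __init__(self, node_name: str, messages: Sequence[str]):
        self.node_name = node_name
        self.messages = tuple(messages)
        super().__init__(f"node {node_name!r} blocked the fit: " + "; ".join(messages))


FAMILIES = ("gaussian", "binomial", "poisson")

_ETA_MAX = 30.0  # log-link linear predictor clamp against overflow
_MU_EPS = 1e-12


def _family_mu(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "gaussian":
        return eta
    if family == "binomial":
        return expit(eta)
    if family == "poisson":
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    raise GLMError(f"unknown family {family!r}; choose one of {FAMILIES}")


def _family_weights(family: str, mu: np.ndarray) -> np.ndarray:
    if family == "gaussian":
        return np.ones_like(mu)
    if family == "binomial":
        return np.clip(mu * (1.0 - mu), _MU_EPS, None)
    return np.clip(mu, _MU_EPS, None)  # poisson


def family_deviance(family: str, y: np.ndarray, mu: np.ndarray) -> float:
    if family == "gaussian":
        return float(np.sum((y - mu) ** 2))
    if family == "binomial":
        mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
        return float(
            2.0
            * np.sum(
                xlogy(y, y) - xlogy(y, mu) + xlogy(1 - y, 1 - y) - xlogy(1 - y, 1 - mu)
            )
        )
    mu = np.clip(mu, _MU_EPS, None)
    return float(2.0 * np.sum(xlogy(y, y) - xlogy(y, mu) - (y - mu)))


# ---------------------------------------------------------------------------
# Model specification

@dataclass(frozen=True)
class GLMSpec:
    """Model formula plus family and IRLS controls.

    The formula mini-syntax is ``"outcome ~ cov1 + cov2"``; ``"outcome ~ 1"``
    fits an intercept-only model and a leading ``0 +`` drops the intercept.
    """

    formula: str
    family: str = "gaussian"
    max_iterations: int = 25
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise GLMError(f"family must be one of {FAMILIES}, got {self.family!r}")
        self.parse_formula()  # validate eagerly

    def parse_formula(self) -> tuple[str, tuple[str, ...], bool]:
        """Return (outcome, covariates, intercept)."""
        if "~" not in self.formula:
            raise GLMError(f"formula {self.formula!r} lacks '~'")
        lhs, rhs = (side.strip() for side in self.formula.split("~", 1))
        if not lhs:
            raise GLMError("formula lacks an outcome")
        intercept = True
        covariates: list[str] = []
        for term in (t.strip() for t in rhs.split("+")):
            if term in ("", "1"):
                continue
            if term in ("0", "-1"):
                intercept = False
            else:
                covariates.append(term)
        if not intercept and not covariates:
            raise GLMError("model has neither intercept nor covariates")
        return lhs, tuple(covariates), intercept

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "family": self.family,
            "max_iterations": self.max_iterations,
            "tolerance": self.tolerance,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "GLMSpec":
        return cls(
            formula=data["formula"],
            family=data.get("family", "gaussian"),
            max_iterations=int(data.get("max_iterations", 25)),
            tolerance=float(data.get("tolerance", 1e-8)),
        )


def design_matrix(
    df: pd.DataFrame, spec: GLMSpec
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Build (y, X, column names) from a data frame, complete-case.

    Categorical covariates (object/category/bool columns) are treatment-coded
    against the lexicographically first level so the coding is deterministic
    and identical across nodes.
    """
    outcome, covariates, intercept = spec.parse_formula()
    for name in (outcome, *covariates):
        if name not in df.columns:
            raise GLMError(f"variable {name!r} not found in the assigned table")
    sub = df[[outcome, *covariates]].dropna()
    if sub.empty:
        raise GLMError("no complete-case rows for the model variables")

    y = _outcome_vector(sub[outcome], spec.family)
    columns: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        columns.append(np.ones(len(sub)))
        names.append("(Intercept)")
    for cov in covariates:
        col = sub[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(str(v) for v in col.unique())
            for level in levels[1:]:  # first level is the baseline
                columns.append((col.astype(str) == level).to_numpy(float))
                names.append(f"{cov}[{level}]")
        else:
            columns.append(col.to_numpy(float))
            names.append(cov)
    X = np.column_stack(columns)
    return y, X, tuple(names)


def _outcome_vector(series: pd.Series, family: str) -> np.ndarray:
    if series.dtype.kind in "OUSb" or isinstance(series.dtype, pd.CategoricalDtype):
        levels = sorted(str(v) for v in series.unique())
        if family != "binomial" or len(levels) != 2:
            raise GLMError(
                f"outcome {series.name!r} is categorical; only a two-level "
                "binomial outcome may be non-numeric"
            )
        return (series.astype(str) == levels[1]).to_numpy(float)
    y = series.to_numpy(float)
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise GLMError("binomial outcome must take values in {0, 1}")
    if family == "poisson" and ((y < 0).any() or not np.allclose(y, np.round(y))):
        raise GLMError("poisson outcome must be a non-negative count")
    return y


# ---------------------------------------------------------------------------
# Per-iteration algebra

def compute_contribution(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, family: str
) -> dict:
    """One node's IRLS normal-equation share at the current ``beta``.

    Returns the weighted information ``X'WX``, the score cross-product
    ``X'Wz`` (``z`` the working response), the complete-case count and the
    deviance at ``beta``. Raises :class:`GLMError` on non-finite weights.
    """
    eta = X @ beta
    mu = _family_mu(family, eta)
    w = _family_weights(family, mu)
    z = eta + (y - mu) / w if family != "gaussian" else y
    if not (np.isfinite(w).all() and np.isfinite(z).all()):
        raise GLMError("non-finite IRLS weights or working response")
    Xw = X * w[:, None]
    info = X.T @ Xw
    score = Xw.T @ z
    return {
        "information": info,
        "score_cross": score,
        "n_obs": int(len(y)),
        "deviance": family_deviance(family, y, mu),
    }


@dataclass
class GLMFit:
    """Federated (or pooled) model result."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    names: tuple[str, ...]
    deviance: float
    iterations: int
    converged: bool
    n_total: int
    per_node_n: dict[str, int]
    family: str
    formula: str

    def to_frame(self) -> pd.DataFrame:
        z = self.coefficients / self.standard_errors
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "term": list(self.names),
                "estimate": self.coefficients,
                "std_error": self.standard_errors,
                "z_value": z,
                "p_value": 2.0 * norm.sf(np.abs(z)),
            }
        )

    def summary(self) -> str:
        lines = [
            f"Federated GLM ({self.family}): {self.formula}",
            f"n = {self.n_total} across {len(self.per_node_n)} node(s) "
            f"{dict(self.per_node_n)}",
            f"deviance = {self.deviance:.6g}, iterations = {self.iterations}, "
            f"converged = {self.converged}",
            self.to_frame().to_string(index=False),
        ]
        return "\n".join(lines)


def _solve_update(info: np.ndarray, score: np.ndarray) -> np.ndarray:
    try:
        beta = np.linalg.solve(info, score)
    except np.linalg.LinAlgError as exc:
        raise NonIdentifiableError("non-identifiable model") from exc
    if not np.isfinite(beta).all():
        raise NonIdentifiableError("non-identifiable model")
    return beta


def _dispersion(family: str, deviance: float, n_obs: int, p: int) -> float:
    """Gaussian fits estimate the dispersion as deviance/(n-p); the binomial
    and poisson families have dispersion fixed at 1."""
    if family == "gaussian":
        if n_obs <= p:
            return 1.0
        return deviance / (n_obs - p)
    return 1.0


def _covariance(info: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise NonIdentifiableError("non-identifiable model") from exc


def fit_irls(
    y: np.ndarray,
    X: np.ndarray,
    family: str,
    max_iterations: int = 25,
    tolerance: float = 1e-8,
) -> dict:
    """Single-machine IRLS with the same loop as the federated client.

    Starts at ``beta = 0`` and stops when the relative deviance change
    ``|dev_t - dev_{t-1}| / (|dev_t| + 0.1)`` drops below ``tolerance``.
    """
    p = X.shape[1]
    beta = np.zeros(p)
    dev_prev = None
    converged = False
    iterations = 0
    info = score = None
    deviance = np.nan
    for iterations in range(1, max_iterations + 1):
        contrib = compute_contribution(y, X, beta, family)
        info, score = contrib["information"], contrib["score_cross"]
        deviance = contrib["deviance"]
        beta_new = _solve_update(info, score)
        if dev_prev is not None and abs(deviance - dev_prev) / (abs(deviance) + 0.1) < tolerance:
            converged = True
            beta = beta_new
            break
        dev_prev = deviance
        beta = beta_new
    dispersion = _dispersion(family, deviance, len(y), p)
    se = np.sqrt(dispersion * np.diag(_covariance(info)))
    return {
        "coefficients": beta,
        "standard_errors": se,
        "deviance": deviance,
        "iterations": iterations,
        "converged": converged,
        "n_obs": int(len(y)),
    }


# ---------------------------------------------------------------------------
# Server-side operations

def _node_design(node, spec: GLMSpec, symbol: str):
    df = node.get_dataset(symbol)
    if not isinstance(df, pd.DataFrame):
        raise GLMError(f"symbol {symbol!r} is not a tabular dataset")
    return design_matrix(df, spec)


@server_op("glm_columns")
def _op_glm_columns(node, symbol: str, spec: Mapping):
    """Design-column names and complete-case count; used by the client to
    verify identical covariate coding across nodes before iterating."""
    y, X, names = _node_design(node, GLMSpec.from_dict(spec), symbol)
    payload = {"columns": list(names), "n_obs": int(len(y))}
    return payload, GuardContext(n_obs=len(y), n_params=len(names))


@server_op("glm_step")
def _op_glm_step(node, symbol: str, spec: Mapping, beta: Sequence[float]):
    glm_spec = GLMSpec.from_dict(spec)
    y, X, names = _node_design(node, glm_spec, symbol)
    contrib = glm_server_contribution(node, glm_spec, y, X, np.asarray(beta, float))
    payload = {
        "information": contrib["information"].tolist(),
        "score_cross": contrib["score_cross"].tolist(),
        "n_obs": contrib["n_obs"],
        "deviance": contrib["deviance"],
    }
    return payload, GuardContext(n_obs=len(y), n_params=len(names))


def glm_server_contribution(node, spec: GLMSpec, y, X, beta) -> dict:
    """Validity-checked per-node contribution (shared by tabular and GWAS
    paths). Raises ``DisclosureBlocked`` when the node's policy forbids the
    fit for this sample size."""
    check_model_validity(len(y), X.shape[1], node.disclosure).raise_if_blocked()
    return compute_contribution(y, X, beta, spec.family)


def glm_server_step(node, spec: GLMSpec, beta: Sequence[float], symbol: str = "D") -> dict:
    """Direct (in-node) form of the per-iteration aggregate; the federated
    client reaches the same computation through the ``glm_step`` request."""
    y, X, _ = _node_design(node, spec, symbol)
    return glm_server_contribution(node, spec, y, X, np.asarray(beta, float))


# ---------------------------------------------------------------------------
# Client-side federated fit

def glm_fit_federated(
    session: ClientSession, spec: GLMSpec, data_symbol: str = "D"
) -> GLMFit:
    """Fit ``spec`` across every node of ``session`` by distributed IRLS.

    Per iteration the client broadcasts the current coefficient vector, each
    node returns its disclosure-checked ``X'WX`` / ``X'Wz`` share, and the
    client solves the summed normal equations. Any node block aborts the fit
    with that node's study-side messages.
    """
    spec_dict = spec.to_dict()
    col_resp = session.broadcast("glm_columns", {"symbol": data_symbol, "spec": spec_dict})
    _raise_on_block(col_resp)
    names = tuple(col_resp[0].payload["columns"])
    for resp in col_resp[1:]:
        if tuple(resp.payload["columns"]) != names:
            raise GLMError(
                "covariate coding mismatch across nodes: "
                f"{resp.node_name!r} disagrees with {col_resp[0].node_name!r}"
            )
    res = _federated_irls(
        session, spec, "glm_step", {"symbol": data_symbol, "spec": spec_dict}, len(names)
    )
    return GLMFit(
        coefficients=res["coefficients"],
        standard_errors=res["standard_errors"],
        names=names,
        deviance=res["deviance"],
        iterations=res["iterations"],
        converged=res["converged"],
        n_total=res["n_total"],
        per_node_n=res["per_node_n"],
        family=spec.family,
        formula=spec.formula,
    )


def _federated_irls(
    session: ClientSession, spec: GLMSpec, op_name: str, base_args: Mapping, p: int
) -> dict:
    """Distributed IRLS driver shared by the tabular and per-SNP fits.

    Broadcasts ``op_name`` with the current beta each iteration, sums the
    per-node information and score shares, and solves the normal equations.
    """
    beta = np.zeros(p)
    dev_prev = None
    converged = False
    iterations = 0
    info_sum = None
    deviance = np.nan
    per_node_n: dict[str, int] = {}
    for iterations in range(1, spec.max_iterations + 1):
        responses = session.broadcast(op_name, {**base_args, "beta": beta.tolist()})
        _raise_on_block(responses)
        info_sum = np.zeros((p, p))
        score_sum = np.zeros(p)
        deviance = 0.0
        for resp in responses:
            info_sum += np.asarray(resp.payload["information"], float)
            score_sum += np.asarray(resp.payload["score_cross"], float)
            deviance += resp.payload["deviance"]
            per_node_n[resp.node_name] = int(resp.payload["n_obs"])
        beta_new = _solve_update(info_sum, score_sum)
        if dev_prev is not None and abs(deviance - dev_prev) / (abs(deviance) + 0.1) < spec.tolerance:
            converged = True
            beta = beta_new
            break
        dev_prev = deviance
        beta = beta_new
    n_total = sum(per_node_n.values())
    dispersion = _dispersion(spec.family, deviance, n_total, p)
    return {
        "coefficients": beta,
        "standard_errors": np.sqrt(dispersion * np.diag(_covariance(info_sum))),
        "deviance": deviance,
        "iterations": iterations,
        "converged": converged,
        "n_total": sum(per_node_n.values()),
        "per_node_n": per_node_n,
    }


def _raise_on_block(responses) -> None:
    for resp in responses:
        if not resp.ok:
            raise FederatedBlockedError(resp.node_name, resp.messages)


def glm_pooled_oracle(tables: Sequence[pd.DataFrame], spec: GLMSpec) -> GLMFit:
    """Single-machine fit on the concatenated rows.

    Runs the identical IRLS loop on the pooled data; the federated fit is
    required to agree with this to numerical precision.
    """
    tables = [t for t in tables if len(t)]
    if not tables:
        raise GLMError("no rows to fit: empty concatenation")
    pooled = pd.concat(tables, ignore_index=True)
    y, X, names = design_matrix(pooled, spec)
    res = fit_irls(y, X, spec.family, spec.max_iterations, spec.tolerance)
    return GLMFit(
        coefficients=res["coefficients"],
        standard_errors=res["standard_errors"],
        names=names,
        deviance=res["deviance"],
        iterations=res["iterations"],
        converged=res["converged"],
        n_total=res["n_obs"],
        per_node_n={"pooled": res["n_obs"]},
        family=spec.family,
        formula=spec.formula,
    )
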