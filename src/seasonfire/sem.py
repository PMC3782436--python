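"""Linear-Gaussian structural equation models over observed variables.

A :class:`PathModel` is a directed acyclic system of regressions among observed
variables: directed edges carry (free or fixed) partial regression
coefficients, every endogenous variable gets a free error variance, exogenous
variables get free variances, and exogenous covariances are fixed at zero
unless explicitly declared.  With A the coefficient matrix and Omega the
(co)variance matrix of exogenous variables and errors, the model-implied
covariance is

    Sigma(theta) = (I - A)^-1 Omega (I - A)^-T.

Fitting minimizes the Wishart maximum-likelihood discrepancy

    F_ML(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p,

with chi^2 = (n - 1) F_ML at the optimum and df = p(p+1)/2 - q free
parameters.  Covariance structure only; no mean structure.

Standardized coefficients are reported in SD units (coefficient times implied
SD of source over implied SD of target), R^2 per endogenous variable is
1 - error variance / implied variance, and direct / indirect / total effects
follow the path-tracing algebra: the total-effects matrix of a standardized
coefficient matrix A is (I - A)^-1 - I, of which A is the direct part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Edge",
    "Covariance",
    "PathModel",
    "SEMFit",
    "implied_covariance",
    "fit_ml",
    "sample_covariance",
    "chisq_pvalue",
    "bcc",
    "aic",
    "effects",
    "effects_table",
    "significance_tier",
    "parse_model_spec",
    "model_spec_text",
]

_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class Edge:
    """Directed edge source -> target; ``value`` fixes the coefficient."""

    source: str
    target: str
    value: float | None = None

    @property
    def free(self) -> bool:
        return self.value is None

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class Covariance:
    """Exogenous covariance a ~~ b; free when ``value`` is None."""

    a: str
    b: str
    value: float | None = None

    @property
    def name(self) -> str:
        return f"{self.a}~~{self.b}"


class PathModel:
    """Directed-edge specification of a recursive linear-Gaussian system."""

    def __init__(self, variables, edges, covariances=(), name: str = ""):
        self.variables = list(variables)
        self.edges = [e if isinstance(e, Edge) else Edge(*e) for e in edges]
        self.covariances = [c if isinstance(c, Covariance) else Covariance(*c) for c in covariances]
        self.name = name
        self._validate()

    def _validate(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        known = set(self.variables)
        seen = set()
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge {e.name} references unknown variable")
            if (e.source, e.target) in seen:
                raise ValueError(f"duplicate edge {e.name}")
            if e.value is not None and not math.isfinite(e.value):
                raise ValueError(f"non-finite fixed value on {e.name}")
            seen.add((e.source, e.target))
            g.add_edge(e.source, e.target)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed part of the model contains a cycle")
        self._graph = g
        endo = self.endogenous
        for c in self.covariances:
            if c.a in endo or c.b in endo:
                raise ValueError(f"covariance {c.name} involves an endogenous variable")
            if c.a == c.b:
                raise ValueError("self-covariance; variances are implicit parameters")

    # --- structure -----------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def endogenous(self) -> list[str]:
        has_in = {e.target for e in self.edges}
        return [v for v in self.variables if v in has_in]

    @property
    def exogenous(self) -> list[str]:
        has_in = {e.target for e in self.edges}
        return [v for v in self.variables if v not in has_in]

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self._graph))

    def parents(self, v: str) -> list[str]:
        return [e.source for e in self.edges if e.target == v]

    # --- parameters ----------------------------------------------------
    @property
    def free_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.free]

    @property
    def free_covariances(self) -> list[Covariance]:
        return [c for c in self.covariances if c.value is None]

    def parameter_names(self) -> list[str]:
        names = [f"beta:{e.name}" for e in self.free_edges]
        names += [f"var:{v}" for v in self.exogenous]
        names += [f"err:{v}" for v in self.endogenous]
        names += [f"cov:{c.name}" for c in self.free_covariances]
        return names

    @property
    def q(self) -> int:
        return len(self.free_edges) + self.p + len(self.free_covariances)

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.q

    def fully_fixed(self) -> bool:
        return not self.free_edges

    # --- matrices ------------------------------------------------------
    def matrices(self, theta: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
        """(A, Omega) for a parameter dict keyed by parameter_names entries."""
        idx = {v: i for i, v in enumerate(self.variables)}
        A = np.zeros((self.p, self.p))
        for e in self.edges:
            A[idx[e.target], idx[e.source]] = e.value if not e.free else theta[f"beta:{e.name}"]
        Om = np.zeros((self.p, self.p))
        for v in self.exogenous:
            Om[idx[v], idx[v]] = theta[f"var:{v}"]
        for v in self.endogenous:
            Om[idx[v], idx[v]] = theta[f"err:{v}"]
        for c in self.covariances:
            val = c.value if c.value is not None else theta[f"cov:{c.name}"]
            Om[idx[c.a], idx[c.b]] = Om[idx[c.b], idx[c.a]] = val
        return A, Om

    def coefficient_matrix(self, coefficients: dict[str, float] | None = None) -> np.ndarray:
        """A matrix from fixed edge values (plus overrides for free edges)."""
        idx = {v: i for i, v in enumerate(self.variables)}
        A = np.zeros((self.p, self.p))
        for e in self.edges:
            if e.free:
                if coefficients is None or e.name not in coefficients:
                    raise ValueError(f"edge {e.name} has no coefficient")
                val = coefficients[e.name]
            else:
                val = e.value
            A[idx[e.target], idx[e.source]] = val
        return A

    def __repr__(self) -> str:
        return f"PathModel({self.name or 'unnamed'}: {self.p} vars, {len(self.edges)} edges, df={self.df})"


def implied_covariance(model: PathModel, theta: dict[str, float]) -> np.ndarray:
    """Sigma(theta) = (I - A)^-1 Omega (I - A)^-T (symmetric by construction)."""
    A, Om = model.matrices(theta)
    B = _inv_i_minus_a(A)
    sigma = B @ Om @ B.T
    return (sigma + sigma.T) / 2.0


def _inv_i_minus_a(A: np.ndarray) -> np.ndarray:
    IA = np.eye(A.shape[0]) - A
    # acyclic A makes I - A unimodular triangular under a topological order,
    # hence invertible; the guard catches malformed fixed values anyway
    if abs(np.linalg.det(IA)) < 1e-12:
        raise np.linalg.LinAlgError("singular I - A")
    return np.linalg.inv(IA)


def sample_covariance(data: pd.DataFrame | np.ndarray, variables=None) -> np.ndarray:
    """Sample covariance with the n-1 denominator, ordered by ``variables``."""
    if isinstance(data, pd.DataFrame):
        if variables is not None:
            data = data.loc[:, list(variables)]
        arr = data.to_numpy(float)
    else:
        arr = np.asarray(data, float)
    return np.cov(arr, rowvar=False, ddof=1)


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------


@dataclass
class SEMFit:
    """Result of an ML covariance-structure fit."""

    model: PathModel
    n: int
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    z_pvalues: dict[str, float]          # per free coefficient, two-sided
    standardized: dict[str, float]       # per edge name, SD units
    implied: np.ndarray
    chisq: float
    df: int
    pvalue: float | None
    bcc: float
    aic: float
    r2: dict[str, float]
    converged: bool
    heywood: bool
    fmin: float

    def r2_endogenous(self, variable: str) -> float:
        if variable not in self.model.endogenous:
            raise ValueError(f"{variable!r} is not endogenous")
        return self.r2[variable]

    def standardized_coefficients(self) -> dict[str, float]:
        return dict(self.standardized)

    def summary(self) -> pd.DataFrame:
        rows = []
        for e in self.model.edges:
            key = f"beta:{e.name}"
            rows.append(
                {
                    "edge": e.name,
                    "estimate": self.estimates.get(key, e.value),
                    "se": self.standard_errors.get(key, np.nan),
                    "p": self.z_pvalues.get(key, np.nan),
                    "standardized": self.standardized[e.name],
                    "tier": significance_tier(self.z_pvalues.get(key, np.nan)),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "n": self.n,
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "z_pvalues": self.z_pvalues,
            "standardized": self.standardized,
            "chisq": self.chisq,
            "df": self.df,
            "pvalue": self.pvalue,
            "bcc": self.bcc,
            "aic": self.aic,
            "r2": self.r2,
            "converged": self.converged,
            "heywood": self.heywood,
        }


def chisq_pvalue(chisq: float, df: int) -> float:
    """Upper-tail central chi-square probability; undefined for df < 1."""
    if df < 1:
        raise ValueError("p-value undefined for df < 1 (saturated model)")
    if chisq < 0:
        raise ValueError("chi-square must be nonnegative")
    return float(stats.chi2.sf(chisq, df))


def bcc(chisq: float, q: int, n: int, p: int) -> float:
    """Browne-Cudeck criterion, single-group covariance form.

    BCC = chi^2 + 2 q (n - 1) / (n - p - 2).  The per-parameter penalty
    2(n-1)/(n-p-2) exceeds AIC's 2 for every admissible n, which is what makes
    the criterion lean harder on complex models.
    """
    if n <= p + 2:
        raise ValueError("BCC requires n > p + 2")
    return chisq + 2.0 * q * (n - 1) / (n - p - 2)


def aic(chisq: float, q: int) -> float:
    return chisq + 2.0 * q


def significance_tier(p: float | None) -> str:
    """Line-weight coding of coefficient significance used in the figures."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "none"
    if p <= 0.001:
        return "thick"
    if p <= 0.01:
        return "medium"
    if p <= 0.05:
        return "thin"
    if p <= 0.10:
        return "gray"
    return "dashed"


class _Parameterization:
    """Internal optimizer coordinates: raw coefficients and covariances,
    log variances (keeps every variance positive along the path)."""

    def __init__(self, model: PathModel):
        self.model = model
        self.names = model.parameter_names()
        self.is_var = np.array([n.startswith(("var:", "err:")) for n in self.names])

    def to_internal(self, theta: dict[str, float]) -> np.ndarray:
        x = np.array([theta[n] for n in self.names], float)
        x[self.is_var] = np.log(np.maximum(x[self.is_var], _VAR_FLOOR))
        return x

    def to_natural(self, x: np.ndarray) -> dict[str, float]:
        vals = x.copy()
        # clip before exponentiating: line searches may probe absurd steps
        vals[self.is_var] = np.exp(np.clip(vals[self.is_var], -40.0, 40.0))
        return dict(zip(self.names, vals))

    def jacobian_diag(self, x: np.ndarray) -> np.ndarray:
        """d(natural)/d(internal), diagonal."""
        d = np.ones_like(x)
        d[self.is_var] = np.exp(np.clip(x[self.is_var], -40.0, 40.0))
        return d


def _fml_and_grad(x, par, model, S, logdet_S):
    theta = par.to_natural(x)
    A, Om = model.matrices(theta)
    p = model.p
    B = _inv_i_minus_a(A)
    Sigma = B @ Om @ B.T
    if not np.all(np.isfinite(Sigma)):
        return 1e10, np.zeros_like(x)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return 1e10, np.zeros_like(x)
    Si = np.linalg.inv(Sigma)
    F = logdet + float(np.sum(Si * S)) - logdet_S - p
    # gradient: dF = tr[C dSigma], C = Sigma^-1 - Sigma^-1 S Sigma^-1
    C = Si - Si @ S @ Si
    idx = {v: i for i, v in enumerate(model.variables)}
    grad = np.zeros_like(x)
    k = 0
    CB = C @ B
    SigC = Sigma @ C
    for e in model.free_edges:
        t, s = idx[e.target], idx[e.source]
        # dSigma = u v' + v u' with u = B[:, t], v = Sigma[s, :]
        grad[k] = 2.0 * float(SigC[s, :] @ B[:, t])
        k += 1
    for v in model.exogenous:
        i = idx[v]
        grad[k] = float(B[:, i] @ CB[:, i])  # tr[C B e_i e_i' B']
        k += 1
    for v in model.endogenous:
        i = idx[v]
        grad[k] = float(B[:, i] @ CB[:, i])
        k += 1
    for c in model.free_covariances:
        i, j = idx[c.a], idx[c.b]
        grad[k] = 2.0 * float(B[:, i] @ CB[:, j])
        k += 1
    grad *= par.jacobian_diag(x)  # chain rule for log-variance coordinates
    return F, grad


def _warm_start(model: PathModel, S: np.ndarray) -> dict[str, float]:
    """Equation-wise least squares on S plus sample moments for the exogenous
    block; exact ML for recursive models with a saturated exogenous block, and
    a good neighborhood otherwise."""
    idx = {v: i for i, v in enumerate(model.variables)}
    theta: dict[str, float] = {}
    for v in model.exogenous:
        theta[f"var:{v}"] = max(S[idx[v], idx[v]], _VAR_FLOOR)
    for c in model.free_covariances:
        theta[f"cov:{c.name}"] = S[idx[c.a], idx[c.b]]
    for v in model.endogenous:
        parents = model.parents(v)
        pi = [idx[u] for u in parents]
        yi = idx[v]
        Spp = S[np.ix_(pi, pi)]
        Spy = S[pi, yi]
        try:
            b = np.linalg.solve(Spp, Spy)
        except np.linalg.LinAlgError:
            b = np.linalg.lstsq(Spp, Spy, rcond=None)[0]
        fixed_adjust = 0.0
        for u, bu in zip(parents, b):
            for e in model.edges:
                if e.target == v and e.source == u:
                    if e.free:
                        theta[f"beta:{e.name}"] = float(bu)
                    else:
                        fixed_adjust += 0.0  # fixed edges keep their value; residual absorbs misfit
        resid = S[yi, yi] - float(b @ Spy)
        theta[f"err:{v}"] = max(resid, 0.05 * S[yi, yi], _VAR_FLOOR)
    return theta


def fit_ml(
    S: np.ndarray | pd.DataFrame,
    model: PathModel,
    n: int,
    n_starts: int = 5,
    gtol: float = 1e-8,
    start_seed: int = 0,
    compute_se: bool = True,
) -> SEMFit:
    """Maximum-likelihood covariance-structure fit.

    Deterministic given inputs: the first start is an equation-wise least
    squares warm start, the remaining ``n_starts - 1`` are fixed seeded
    perturbations of it; the best converged optimum is kept.
    """
    if isinstance(S, pd.DataFrame):
        S = S.loc[model.variables, model.variables].to_numpy(float)
    S = np.asarray(S, float)
    p = model.p
    if S.shape != (p, p):
        raise ValueError(f"S must be {p}x{p} in the model's variable order")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    eigmin = np.linalg.eigvalsh(S).min()
    if eigmin <= 0:
        raise ValueError("S must be positive definite")
    if n <= p:
        raise ValueError("sample size must exceed the number of variables")
    if model.df < 0:
        raise ValueError(f"model not identified: df = {model.df} < 0")

    par = _Parameterization(model)
    sign, logdet_S = np.linalg.slogdet(S)
    x0 = par.to_internal(_warm_start(model, S))
    rng = np.random.default_rng(start_seed)
    best = None
    for k in range(max(1, n_starts)):
        xk = x0 if k == 0 else x0 + 0.1 * k * rng.standard_normal(x0.size)
        res = optimize.minimize(
            _fml_and_grad,
            xk,
            args=(par, model, S, logdet_S),
            jac=True,
            method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        ok = grad_norm < 1e-5 or res.success
        if best is None or (ok and res.fun < best[0].fun - 1e-12):
            best = (res, ok)
        elif ok and not best[1]:
            best = (res, ok)
    res, converged = best
    fmin = max(float(res.fun), 0.0)
    theta = par.to_natural(res.x)

    Sigma = implied_covariance(model, theta)
    chisq = max((n - 1) * fmin, 0.0)
    df = model.df
    pvalue = chisq_pvalue(chisq, df) if df >= 1 else None

    # standard errors: acov(theta_internal) = (2/(n-1)) H^-1, delta method out
    if compute_se:
        se, zp = _standard_errors(res.x, par, model, S, logdet_S, n)
    else:
        se, zp = {}, {}

    idx = {v: i for i, v in enumerate(model.variables)}
    sds = np.sqrt(np.clip(np.diag(Sigma), _VAR_FLOOR, None))
    standardized = {}
    for e in model.edges:
        raw = theta[f"beta:{e.name}"] if e.free else e.value
        standardized[e.name] = raw * sds[idx[e.source]] / sds[idx[e.target]]
    r2 = {}
    heywood = False
    for v in model.endogenous:
        err = theta[f"err:{v}"]
        tot = Sigma[idx[v], idx[v]]
        r2[v] = 1.0 - err / tot
        if err <= 10 * _VAR_FLOOR:
            heywood = True
    for v in model.exogenous:
        if theta[f"var:{v}"] <= 10 * _VAR_FLOOR:
            heywood = True

    return SEMFit(
        model=model,
        n=n,
        estimates=theta,
        standard_errors=se,
        z_pvalues=zp,
        standardized=standardized,
        implied=Sigma,
        chisq=chisq,
        df=df,
        pvalue=pvalue,
        bcc=bcc(chisq, model.q, n, p),
        aic=aic(chisq, model.q),
        r2=r2,
        converged=bool(converged),
        heywood=heywood,
        fmin=fmin,
    )


def _standard_errors(x, par, model, S, logdet_S, n):
    """Finite-difference Hessian of F_ML at the optimum -> asymptotic SEs."""
    m = x.size
    eps = 1e-5
    H = np.zeros((m, m))
    for j in range(m):
        xp = x.copy(); xp[j] += eps
        xm = x.copy(); xm[j] -= eps
        _, gp = _fml_and_grad(xp, par, model, S, logdet_S)
        _, gm = _fml_and_grad(xm, par, model, S, logdet_S)
        H[:, j] = (gp - gm) / (2 * eps)
    H = (H + H.T) / 2.0
    se = {}
    zp = {}
    try:
        acov = (2.0 / (n - 1)) * np.linalg.inv(H)
        dvar = np.clip(np.diag(acov), 0.0, None)
        jac = par.jacobian_diag(x)
        se_all = np.sqrt(dvar) * jac  # delta method for log-variance coords
        theta = par.to_natural(x)
        for name, s in zip(par.names, se_all):
            se[name] = float(s)
            if name.startswith("beta:") and s > 0:
                z = theta[name] / s
                zp[name] = float(2.0 * stats.norm.sf(abs(z)))
    except np.linalg.LinAlgError:
        se = {name: float("nan") for name in par.names}
        zp = {f"beta:{e.name}": float("nan") for e in model.free_edges}
    return se, zp


# ---------------------------------------------------------------------------
# Effect decomposition
# ---------------------------------------------------------------------------


def effects_table(model: PathModel, coefficients: dict[str, float] | None = None) -> pd.DataFrame:
    """Direct / indirect / total standardized effects for every ordered pair.

    ``coefficients`` supplies values for free edges (fitted models pass their
    standardized coefficients); fully fixed catalog models need none.  Total
    effects are [(I - A)^-1 - I], directs are A, indirects the difference --
    equivalently the sum over all directed paths of length >= 2 of the product
    of coefficients along each path.
    """
    A = model.coefficient_matrix(coefficients)
    total = _inv_i_minus_a(A) - np.eye(model.p)
    indirect = total - A
    rows = []
    for i, tgt in enumerate(model.variables):
        for j, src in enumerate(model.variables):
            if src == tgt:
                continue
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "direct": A[i, j],
                    "indirect": indirect[i, j],
                    "total": total[i, j],
                }
            )
    return pd.DataFrame(rows).set_index(["source", "target"])


def effects(model_or_fit, source: str, target: str) -> dict[str, float]:
    """One EffectTable row: direct, indirect, total from source to target."""
    if isinstance(model_or_fit, SEMFit):
        model = model_or_fit.model
        coeffs = model_or_fit.standardized
    else:
        model = model_or_fit
        coeffs = None
    if source not in model.variables or target not in model.variables:
        raise ValueError("source/target not in model")
    table = effects_table(model, coeffs)
    row = table.loc[(source, target)]
    return {"direct": float(row["direct"]), "indirect": float(row["indirect"]), "total": float(row["total"])}


# ---------------------------------------------------------------------------
# Declarative model-spec format
# ---------------------------------------------------------------------------


def parse_model_spec(text: str, name: str = "") -> tuple[PathModel, dict]:
    """Parse the declarative edge-list model format.

    Lines (``#`` comments allowed)::

        vars nino onset duration rainfall tc
        role fitted-best
        onset -> duration fixed=-0.69
        nino -> tc fixed=-0.25 placeholder
        duration -> rainfall free
        rainfall -> tc free optional
        cov nino ~~ onset free

    Returns the PathModel plus metadata: role, per-edge provenance
    (``printed`` for fixed values, ``placeholder`` when so marked), and the
    optional-edge names used by specification-search frameworks.
    """
    variables: list[str] = []
    edges: list[Edge] = []
    covs: list[Covariance] = []
    role = ""
    provenance: dict[str, str] = {}
    optional: list[str] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if tokens[0] == "vars":
            variables = tokens[1:]
        elif tokens[0] == "role":
            role = tokens[1]
        elif tokens[0] == "cov":
            if len(tokens) < 4 or tokens[2] != "~~":
                raise ValueError(f"bad covariance line: {raw!r}")
            value = None
            if len(tokens) > 4 and tokens[4].startswith("fixed="):
                value = float(tokens[4].split("=", 1)[1])
            covs.append(Covariance(tokens[1], tokens[3], value))
        elif len(tokens) >= 3 and tokens[1] == "->":
            src, tgt = tokens[0], tokens[2]
            value = None
            flags = tokens[3:]
            for f in flags:
                if f.startswith("fixed="):
                    value = float(f.split("=", 1)[1])
            edge = Edge(src, tgt, value)
            edges.append(edge)
            if value is not None:
                provenance[edge.name] = "placeholder" if "placeholder" in flags else "printed"
            if "optional" in flags:
                optional.append(edge.name)
        else:
            raise ValueError(f"cannot parse model spec line: {raw!r}")
    if not variables:
        raise ValueError("model spec lacks a 'vars' line")
    model = PathModel(variables, edges, covs, name=name)
    return model, {"role": role, "provenance": provenance, "optional_edges": optional}


def model_spec_text(model: PathModel, role: str = "") -> str:
    """Serialize a PathModel back to the declarative format."""
    lines = [f"vars {' '.join(model.variables)}"]
    if role:
        lines.append(f"role {role}")
    for e in model.edges:
        tail = "free" if e.free else f"fixed={e.value:g}"
        lines.append(f"{e.source} -> {e.target} {tail}")
    for c in model.covariances:
        tail = "free" if c.value is None else f"fixed={c.value:g}"
        lines.append(f"cov {c.a} ~~ {c.b} {tail}")
    return "\n".join(lines) + "\n"
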