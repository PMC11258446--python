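"""Self-contained degree-2 multivariate adaptive regression splines.

Forward pass greedily adds reflected hinge pairs ``max(0, +-(x_v - t))``
multiplied into an existing parent term (degree capped at 2), backward
pruning deletes terms by generalized cross-validation, and variable
importance scores the GCV increase when a variable's terms are dropped.

Candidate knots default to up to ``max_knots_per_var`` equally spaced
quantiles of each variable (restricted to the region where the parent
term is active); ``exhaustive=True`` uses every observed value instead,
which is what the brute-force oracle tests rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class MarsError(ValueError):
    pass


@dataclass(frozen=True)
class HingeFactor:
    var: int
    knot: float
    direction: int  # +1 or -1

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.direction * (X[:, self.var] - self.knot))


@dataclass(frozen=True)
class HingeTerm:
    factors: tuple[HingeFactor, ...] = ()

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def variables(self) -> set[int]:
        return {f.var for f in self.factors}

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        out = np.ones(X.shape[0])
        for f in self.factors:
            out = out * f.evaluate(X)
        return out


@dataclass
class MarsModel:
    terms: list[HingeTerm]          # terms[0] is the intercept
    coefficients: np.ndarray
    gcv: float
    n_train: int
    penalty: float = 3.0

    def basis(self, X: np.ndarray) -> np.ndarray:
        n_vars_needed = max((f.var for t in self.terms for f in t.factors), default=-1)
        if X.shape[1] <= n_vars_needed:
            raise MarsError(
                f"model references variable {n_vars_needed} but X has {X.shape[1]} columns"
            )
        return np.column_stack([t.evaluate(X) for t in self.terms])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.basis(np.asarray(X, dtype=float)) @ self.coefficients

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "metaboage.mars/1",
                "penalty": self.penalty,
                "n_train": self.n_train,
                "gcv": self.gcv,
                "terms": [
                    [[f.var, f.knot, f.direction] for f in t.factors] for t in self.terms
                ],
                "coefficients": list(self.coefficients),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "MarsModel":
        d = json.loads(s)
        terms = [
            HingeTerm(tuple(HingeFactor(int(v), float(k), int(dr)) for v, k, dr in t))
            for t in d["terms"]
        ]
        return cls(
            terms=terms,
            coefficients=np.asarray(d["coefficients"], dtype=float),
            gcv=float(d["gcv"]),
            n_train=int(d["n_train"]),
            penalty=float(d.get("penalty", 3.0)),
        )


def effective_params(n_terms: int, penalty: float = 3.0) -> float:
    """GCV cost C(M) = M + penalty * (M - 1) / 2 for M basis terms."""
    return n_terms + penalty * (n_terms - 1) / 2.0


def gcv_score(rss: float, n: int, n_terms: int, penalty: float = 3.0) -> float:
    c = effective_params(n_terms, penalty)
    if c >= n:
        return np.inf
    return (rss / n) / (1.0 - c / n) ** 2


def _knot_candidates(x: np.ndarray, active: np.ndarray, max_knots: int,
                     exhaustive: bool) -> np.ndarray:
    vals = np.unique(x[active])
    if len(vals) < 2:
        return np.empty(0)
    vals = vals[:-1]  # a knot at the max makes the +hinge identically zero
    if exhaustive or len(vals) <= max_knots:
        return vals
    qs = np.linspace(0, 1, max_knots + 2)[1:-1]
    return np.unique(np.quantile(x[active], qs))


def _orthonormal_extend(Q: np.ndarray, c: np.ndarray) -> np.ndarray | None:
    """Gram-Schmidt a column into orthonormal basis Q; None if degenerate."""
    u = c - Q @ (Q.T @ c)
    u = u - Q @ (Q.T @ u)  # reorthogonalize
    nrm = np.linalg.norm(u)
    if nrm < 1e-10 * max(1.0, np.linalg.norm(c)):
        return None
    return u / nrm


def forward_pass(
    X: np.ndarray,
    y: np.ndarray,
    max_terms: int = 21,
    max_knots_per_var: int = 31,
    max_degree: int = 2,
    min_improvement: float = 1e-4,
    exhaustive: bool = False,
    penalty: float = 3.0,
) -> MarsModel:
    """Greedy forward construction of the (unpruned) hinge basis.

    Each step scans (parent term, variable not in parent, knot) triples and
    adds the reflected pair minimizing the residual sum of squares; stops at
    ``max_terms`` total terms or when the relative RSS improvement falls
    below ``min_improvement``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= max_terms:
        raise MarsError("need n > max_terms")
    if not np.all(np.isfinite(X)):
        raise MarsError("X must be finite")

    terms: list[HingeTerm] = [HingeTerm()]
    B = np.ones((n, 1))
    Q = B / np.sqrt(n)
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)
    sst = rss

    while len(terms) + 2 <= max_terms:
        best = None  # (rss_decrease, parent_idx, var, knot)
        for pi, parent in enumerate(terms):
            if parent.degree >= max_degree:
                continue
            pv = B[:, pi]
            active = pv > 0
            if active.sum() < 2:
                continue
            for v in range(p):
                if v in parent.variables:
                    continue
                knots = _knot_candidates(X[:, v], active, max_knots_per_var, exhaustive)
                if len(knots) == 0:
                    continue
                xv = X[:, v]
                C1 = pv[:, None] * np.maximum(0.0, xv[:, None] - knots[None, :])
                C2 = pv[:, None] * np.maximum(0.0, knots[None, :] - xv[:, None])
                Qt1 = Q.T @ C1
                Qt2 = Q.T @ C2
                u11 = np.einsum("ij,ij->j", C1, C1) - np.einsum("ij,ij->j", Qt1, Qt1)
                u22 = np.einsum("ij,ij->j", C2, C2) - np.einsum("ij,ij->j", Qt2, Qt2)
                u12 = np.einsum("ij,ij->j", C1, C2) - np.einsum("ij,ij->j", Qt1, Qt2)
                b1 = C1.T @ r
                b2 = C2.T @ r
                scale = np.maximum(u11, u22)
                # joint 2x2 decrease where well conditioned
                det = u11 * u22 - u12 ** 2
                ok2 = det > 1e-10 * np.maximum(scale ** 2, 1e-30)
                with np.errstate(divide="ignore", invalid="ignore"):
                    dec2 = np.where(
                        ok2,
                        (u22 * b1 ** 2 - 2 * u12 * b1 * b2 + u11 * b2 ** 2)
                        / np.where(ok2, det, 1.0),
                        -np.inf,
                    )
                    dec1 = np.where(u11 > 1e-12 * np.maximum(scale, 1e-30),
                                    b1 ** 2 / u11, -np.inf)
                    decm = np.where(u22 > 1e-12 * np.maximum(scale, 1e-30),
                                    b2 ** 2 / u22, -np.inf)
                dec = np.maximum(dec2, np.maximum(dec1, decm))
                ki = int(np.argmax(dec))
                if dec[ki] > 0 and (best is None or dec[ki] > best[0]):
                    best = (float(dec[ki]), pi, v, float(knots[ki]))
        if best is None:
            break
        decrease, pi, v, knot = best
        if sst > 0 and decrease / sst < min_improvement:
            break
        parent = terms[pi]
        added = False
        for direction in (+1, -1):
            term = HingeTerm(parent.factors + (HingeFactor(v, knot, direction),))
            col = term.evaluate(X)
            qcol = _orthonormal_extend(Q, col)
            if qcol is None:
                continue
            terms.append(term)
            B = np.column_stack([B, col])
            Q = np.column_stack([Q, qcol])
            added = True
            if len(terms) >= max_terms:
                break
        if not added:
            break
        r = y - Q @ (Q.T @ y)
        new_rss = float(r @ r)
        if rss > 0 and (rss - new_rss) / max(sst, 1e-300) < min_improvement:
            rss = new_rss
            break
        rss = new_rss

    coef, rss_fit = _ls_coef(B, y)
    model = MarsModel(
        terms=terms,
        coefficients=coef,
        gcv=gcv_score(rss_fit, n, len(terms), penalty),
        n_train=n,
        penalty=penalty,
    )
    return model


def _ls_coef(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def backward_prune(model: MarsModel, X: np.ndarray, y: np.ndarray) -> MarsModel:
    """Delete terms one at a time, each step removing the term whose
    deletion minimizes GCV; return the minimum-GCV submodel on the path."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(model.terms) < 2:
        raise MarsError("nothing to prune: model has no non-intercept terms")
    if effective_params(len(model.terms), model.penalty) >= n:
        raise MarsError("model is overparameterized: C(M) >= n")

    B_full = model.basis(X)
    active = list(range(len(model.terms)))
    coef, rss = _ls_coef(B_full[:, active], y)
    best = (gcv_score(rss, n, len(active), model.penalty), list(active), coef)

    while len(active) > 1:
        cand_best = None
        for drop in active[1:]:
            sub = [i for i in active if i != drop]
            coef_s, rss_s = _ls_coef(B_full[:, sub], y)
            g = gcv_score(rss_s, n, len(sub), model.penalty)
            if cand_best is None or g < cand_best[0]:
                cand_best = (g, sub, coef_s)
        active = cand_best[1]
        if cand_best[0] < best[0]:
            best = cand_best

    g, keep, coef = best
    return MarsModel(
        terms=[model.terms[i] for i in keep],
        coefficients=coef,
        gcv=g,
        n_train=n,
        penalty=model.penalty,
    )


def predict(model: MarsModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def variable_importance(model: MarsModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-variable GCV increase when all terms involving the variable are
    removed (with refit), rescaled so the top variable scores 100."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = X.shape[1]
    B = model.basis(X)
    coef, rss = _ls_coef(B, y)
    g0 = gcv_score(rss, n, len(model.terms), model.penalty)
    raw = np.zeros(p)
    used = set().union(*(t.variables for t in model.terms)) if model.terms else set()
    for v in range(p):
        if v not in used:
            continue
        keep = [i for i, t in enumerate(model.terms) if v not in t.variables]
        coef_s, rss_s = _ls_coef(B[:, keep], y)
        g = gcv_score(rss_s, n, len(keep), model.penalty)
        raw[v] = max(0.0, g - g0)
    top = raw.max()
    if top > 0:
        raw = raw / top * 100.0
    return raw
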