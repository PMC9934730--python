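"""Uncertainty analysis for valve-model inputs.

Two complementary tracks:

* a traditional one-at-a-time (OAT) sweep — each parameter sampled at
  uniformly spaced levels across +/-50% of its reference value while the
  others stay at reference; and
* a statistical track — a polynomial chaos expansion (PCE) in orthonormal
  Legendre polynomials fitted by least squares on a weighted approximate
  Fekete point (WAFP) design, from which first- and total-order Sobol
  sensitivity indices follow directly from the squared spectral
  coefficients.

Inputs are treated as independent and uniform on their ranges, so the
natural basis is the tensorized Legendre family on the affinely mapped
cube [-1, 1]^d.  A rank-ordering consistency analysis (column-wise ranks
plus pairwise Kendall tau) summarizes whether the relative ordering of a
metric across model conditions is preserved across scenarios such as
material variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import legval
from scipy.linalg import qr
from scipy.stats import kendalltau, rankdata, skew

from .material import REFERENCE_MITRAL

__all__ = [
    "ParameterSpace",
    "DesignMatrix",
    "PCEModel",
    "SensitivityResult",
    "OrderingResult",
    "oat_design",
    "wafp_design",
    "fit_pce",
    "total_sobol",
    "run_study",
    "ordering_consistency",
    "oat_summary",
    "total_degree_indices",
]


@dataclass(frozen=True)
class ParameterSpace:
    """Named parameters with reference values and a hyperrectangular range."""

    names: tuple
    reference: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        for attr in ("reference", "lower", "upper"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=np.float64))
        d = len(self.names)
        if not (len(self.reference) == len(self.lower) == len(self.upper) == d):
            raise ValueError("names/reference/lower/upper length mismatch")
        if not np.all((self.lower < self.reference) & (self.reference < self.upper)):
            raise ValueError("need lower < reference < upper componentwise")

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        """Affine map from the parameter box to [-1, 1]^d."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        return 2.0 * (x - self.lower) / (self.upper - self.lower) - 1.0

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(np.asarray(u, dtype=np.float64))
        return self.lower + (u + 1.0) * 0.5 * (self.upper - self.lower)

    @classmethod
    def from_reference(cls, names, reference, rel_range: float = 0.5) -> "ParameterSpace":
        """Range = reference -/+ ``rel_range`` (default the +/-50% convention)."""
        ref = np.asarray(reference, dtype=np.float64)
        return cls(tuple(names), ref, ref * (1.0 - rel_range), ref * (1.0 + rel_range))

    @classmethod
    def mitral_default(cls) -> "ParameterSpace":
        """Lee-Sacks coefficients + leaflet thickness at +/-50% of reference."""
        m = REFERENCE_MITRAL
        return cls.from_reference(
            ("c0", "c1", "c2", "thickness"), (m.c0, m.c1, m.c2, m.thickness), 0.5
        )


@dataclass(frozen=True)
class DesignMatrix:
    kind: str  # "oat" or "wafp"
    rows: np.ndarray  # (n, d) parameter vectors
    space: ParameterSpace
    row_meta: list = field(default_factory=list)  # OAT: (parameter name, level index)

    def __post_init__(self):
        rows = np.atleast_2d(np.asarray(self.rows, dtype=np.float64))
        object.__setattr__(self, "rows", rows)
        eps = 1e-9 * (self.space.upper - self.space.lower)
        if np.any(rows < self.space.lower - eps) or np.any(rows > self.space.upper + eps):
            raise ValueError("design rows fall outside the parameter box")

    def __len__(self) -> int:
        return len(self.rows)


def oat_design(space: ParameterSpace, n_levels: int = 5) -> DesignMatrix:
    """One-at-a-time sweep: ``n_levels`` uniform levels per parameter.

    Each row varies exactly one coordinate from the reference point; with an
    odd number of levels the reference value itself is one of them, so the
    reference run is repeated once per parameter (4 parameters x 5 levels =
    20 rows for the default mitral space).
    """
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    rows, meta = [], []
    for j, name in enumerate(space.names):
        levels = np.linspace(space.lower[j], space.upper[j], n_levels)
        for k, val in enumerate(levels):
            row = space.reference.copy()
            row[j] = val
            rows.append(row)
            meta.append((name, k))
    return DesignMatrix("oat", np.asarray(rows), space, meta)


def total_degree_indices(dim: int, order: int) -> np.ndarray:
    """All multi-indices in ``dim`` dimensions with total degree <= ``order``."""
    idx = [()]
    for _ in range(dim):
        idx = [t + (k,) for t in idx for k in range(order + 1 - sum(t))]
    out = np.asarray(sorted(idx, key=lambda t: (sum(t), t)), dtype=np.int64)
    return out.reshape(-1, dim)


def _legendre_basis(u: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Orthonormal Legendre tensor basis evaluated at unit-cube points.

    Orthonormal w.r.t. the uniform probability measure on [-1, 1]^d:
    each 1-D factor is sqrt(2k+1) * P_k.
    """
    u = np.atleast_2d(u)
    n, d = u.shape
    kmax = int(indices.max()) if indices.size else 0
    # per-dimension table of P_0..P_kmax at all points
    per_dim = np.empty((d, kmax + 1, n))
    for j in range(d):
        for k in range(kmax + 1):
            c = np.zeros(k + 1)
            c[k] = np.sqrt(2 * k + 1)
            per_dim[j, k] = legval(u[:, j], c)
    V = np.ones((n, len(indices)))
    for t, mi in enumerate(indices):
        for j, k in enumerate(mi):
            if k:
                V[:, t] *= per_dim[j, k]
    return V


def wafp_design(
    space: ParameterSpace,
    n_samples: int = 80,
    order: int = 3,
    candidate_pool: int | np.ndarray = 2000,
    seed: int = 0,
) -> DesignMatrix:
    """Weighted approximate Fekete point design for least-squares PCE.

    A seeded uniform candidate pool in the parameter box (or an explicit
    array of candidates) is ranked by greedy determinant maximization:
    pivoted QR on the transpose of the Christoffel-weighted Legendre
    Vandermonde.  The first ``n_samples`` pivots form the design.
    """
    indices = total_degree_indices(space.dim, order)
    n_basis = len(indices)
    if n_samples < n_basis:
        raise ValueError(
            f"n_samples={n_samples} is below the basis size {n_basis} at order {order}")
    if isinstance(candidate_pool, (int, np.integer)):
        rng = np.random.default_rng(seed)
        pool = int(candidate_pool)
        if pool < n_samples:
            raise ValueError("candidate pool smaller than the requested design")
        candidates = space.from_unit(rng.uniform(-1.0, 1.0, size=(pool, space.dim)))
    else:
        candidates = np.atleast_2d(np.asarray(candidate_pool, dtype=np.float64))
        if len(candidates) < n_samples:
            raise ValueError("candidate pool smaller than the requested design")
    u = space.to_unit(candidates)
    V = _legendre_basis(u, indices)
    # Christoffel-style row weights equalize the basis energy across candidates
    w = np.sqrt(n_basis) / np.linalg.norm(V, axis=1)
    _, _, piv = qr((V * w[:, None]).T, mode="economic", pivoting=True)
    chosen = np.sort(piv[:n_samples])
    rows = candidates[chosen]
    if np.linalg.matrix_rank(_legendre_basis(space.to_unit(rows), indices)) < n_basis:
        raise RuntimeError("WAFP selection produced a rank-deficient design")
    return DesignMatrix("wafp", rows, space, [("wafp", int(i)) for i in chosen])


@dataclass(frozen=True)
class PCEModel:
    order: int
    basis_index_set: np.ndarray  # (n_basis, d) multi-indices
    coefficients: np.ndarray  # orthonormal-basis coefficients
    domain: ParameterSpace

    def predict(self, x: np.ndarray) -> np.ndarray:
        V = _legendre_basis(self.domain.to_unit(x), self.basis_index_set)
        return V @ self.coefficients

    @property
    def mean(self) -> float:
        return float(self.coefficients[0])

    @property
    def variance(self) -> float:
        return float(np.sum(self.coefficients[1:] ** 2))


def fit_pce(design: DesignMatrix, outputs: np.ndarray, order: int) -> PCEModel:
    """Least-squares Legendre PCE on a design; exact for polynomial outputs."""
    y = np.asarray(outputs, dtype=np.float64).ravel()
    if len(y) != len(design):
        raise ValueError("outputs length does not match the design")
    indices = total_degree_indices(design.space.dim, order)
    if len(y) < len(indices):
        raise ValueError(
            f"{len(y)} samples cannot determine {len(indices)} basis coefficients")
    V = _legendre_basis(design.space.to_unit(design.rows), indices)
    if np.linalg.matrix_rank(V) < len(indices):
        raise ValueError("rank-deficient design for the requested PCE order")
    coeffs, *_ = np.linalg.lstsq(V, y, rcond=None)
    # multi-indices are generated in a deterministic graded order; (0,...,0) first
    assert not indices[0].any()
    return PCEModel(order=order, basis_index_set=indices, coefficients=coeffs, domain=design.space)


@dataclass(frozen=True)
class SensitivityResult:
    names: tuple
    first_order: np.ndarray  # S_i
    total_order: np.ndarray  # S_T,i
    variance: float
    mean: float


def total_sobol(model: PCEModel) -> SensitivityResult:
    """First- and total-order Sobol indices from PCE coefficients.

    With an orthonormal basis the output variance decomposes over the
    non-constant multi-indices; S_i collects terms involving only input i,
    S_T,i collects every term in which input i is active.
    """
    var = model.variance
    if var <= 0:
        raise ValueError("model variance is zero; sensitivity indices undefined")
    mi = model.basis_index_set
    c2 = model.coefficients**2
    active = mi > 0
    d = mi.shape[1]
    first = np.empty(d)
    total = np.empty(d)
    for i in range(d):
        only_i = active[:, i] & (active.sum(axis=1) == 1)
        first[i] = c2[only_i].sum() / var
        total[i] = c2[active[:, i]].sum() / var
    return SensitivityResult(
        names=model.domain.names, first_order=first, total_order=total,
        variance=var, mean=model.mean,
    )


def run_study(design: DesignMatrix, qoi) -> pd.DataFrame:
    """Evaluate a quantity-of-interest callable on every design row.

    Per-row failures are recorded (ok=False, error message) rather than
    raised, so a single bad evaluation does not void a study; a study in
    which *every* row fails raises.
    """
    records = []
    for i, row in enumerate(design.rows):
        rec = {name: val for name, val in zip(design.space.names, row)}
        rec["row"] = i
        if design.kind == "oat" and design.row_meta:
            rec["varied"], rec["level"] = design.row_meta[i]
        try:
            rec["output"] = float(qoi(row))
            rec["ok"] = True
            rec["error"] = ""
        except Exception as exc:  # noqa: BLE001 - fault isolation per row
            rec["output"] = np.nan
            rec["ok"] = False
            rec["error"] = str(exc)
        records.append(rec)
    table = pd.DataFrame(records)
    if not table["ok"].any():
        raise RuntimeError("every design row failed to evaluate")
    return table


def oat_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter dispersion of an OAT study table from :func:`run_study`.

    Reports, per swept parameter: the output range relative to the absolute
    mean output, and the adjusted Fisher-Pearson sample skewness of the
    outputs along the sweep.
    """
    if "varied" not in table:
        raise ValueError("table does not look like an OAT study (missing 'varied')")
    out = []
    for name, grp in table[table["ok"]].groupby("varied", sort=False):
        y = grp["output"].to_numpy()
        scale = abs(y.mean())
        # a flat sweep (parameter does not enter the QoI) has no defined skew
        flat = np.ptp(y) <= 1e-12 * max(scale, 1.0)
        out.append({
            "parameter": name,
            "rel_range": float(np.ptp(y) / scale) if scale > 0 else np.nan,
            "skewness": float(skew(y, bias=False)) if len(y) > 2 and not flat else np.nan,
        })
    return pd.DataFrame(out)


@dataclass(frozen=True)
class OrderingResult:
    ranks: np.ndarray  # (n_conditions, n_scenarios) average ranks per column
    preserved: bool  # all scenario columns share one rank vector
    kendall_tau: np.ndarray  # (n_scenarios, n_scenarios) pairwise tau
    constant_columns: np.ndarray  # bool per scenario


def ordering_consistency(metric_matrix: np.ndarray) -> OrderingResult:
    """Is the ranking of conditions (rows) preserved across scenarios (columns)?"""
    m = np.atleast_2d(np.asarray(metric_matrix, dtype=np.float64))
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 conditions and 2 scenarios")
    if not np.isfinite(m).all():
        raise ValueError("metric matrix contains missing/non-finite entries")
    ranks = np.column_stack([rankdata(m[:, j]) for j in range(m.shape[1])])
    constant = np.array([np.ptp(m[:, j]) == 0.0 for j in range(m.shape[1])])
    preserved = bool(np.all(ranks == ranks[:, [0]])) and not constant.any()
    n = m.shape[1]
    tau = np.ones((n, n))
    for a, b in combinations(range(n), 2):
        t = kendalltau(m[:, a], m[:, b]).statistic
        tau[a, b] = tau[b, a] = t
    return OrderingResult(ranks=ranks, preserved=preserved,
                          kendall_tau=tau, constant_columns=constant)
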