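"""Empirical (cross-)semivariograms and linear-model-of-coregionalization fitting.

The spatial dependence of the pollutant field (Z1, ground PM2.5) and the
covariate field (Z2, satellite aerosol optical depth) is summarised by direct
and cross semivariograms and modelled jointly by a linear model of
coregionalization (LMC): a shared set of elementary correlation structures,
each weighted by a 2x2 positive-semidefinite coefficient matrix.  Validity of
every coefficient matrix is what guarantees that the cokriging system built
from the model is well posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

__all__ = [
    "VariogramStructure",
    "CoregionalizationModel",
    "EmpiricalVariogram",
    "empirical_variogram",
    "empirical_cross_variogram",
    "fit_variogram_model",
    "fit_lmc",
]

FAMILIES = ("nugget", "spherical", "exponential", "gaussian")

#: component labels: direct primary, direct secondary, cross
COMPONENTS = ("11", "22", "12")

_COMP_IDX = {"11": (0, 0), "22": (1, 1), "12": (0, 1), "21": (1, 0)}


def _unit_variogram(family: str, h: np.ndarray, rng: float) -> np.ndarray:
    """Unit-sill semivariogram value gamma(h) for one elementary structure.

    Exponential and gaussian use the practical-range convention: the stated
    range is the distance at which the structure reaches 95% of its sill.
    """
    h = np.asarray(h, dtype=float)
    if family == "nugget":
        return np.where(h > 0.0, 1.0, 0.0)
    if rng <= 0.0:
        raise ValueError(f"structure family {family!r} requires range > 0")
    u = h / rng
    if family == "spherical":
        g = np.where(u < 1.0, 1.5 * u - 0.5 * u**3, 1.0)
    elif family == "exponential":
        g = 1.0 - np.exp(-3.0 * u)
    elif family == "gaussian":
        g = 1.0 - np.exp(-3.0 * u**2)
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    return g


@dataclass(frozen=True)
class VariogramStructure:
    """One elementary structure of a (co)variogram model.

    Parameters
    ----------
    family
        One of ``nugget``, ``spherical``, ``exponential``, ``gaussian``.
    range_km
        Practical range in km; 0 for the nugget.
    """

    family: str
    range_km: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.family == "nugget":
            if self.range_km != 0.0:
                raise ValueError("nugget structure must have range 0")
        elif self.range_km <= 0.0:
            raise ValueError(f"{self.family} structure requires range > 0")

    def unit_variogram(self, h: np.ndarray) -> np.ndarray:
        return _unit_variogram(self.family, h, self.range_km)

    def unit_correlogram(self, h: np.ndarray) -> np.ndarray:
        """rho(h) = 1 - gamma(h); nugget contributes only at exactly h = 0."""
        return 1.0 - self.unit_variogram(h)


class CoregionalizationModel:
    """LMC: ordered structures plus one 2x2 PSD coefficient matrix each.

    ``b_mats[k][a, b]`` is the sill contribution of structure ``k`` to the
    (a, b) component, with index 0 = primary (PM2.5) and 1 = secondary (AOD).
    """

    def __init__(
        self,
        structures: list[VariogramStructure],
        b_mats: list[np.ndarray] | np.ndarray,
        *,
        psd_tol: float = 1e-10,
        converged: bool = True,
    ):
        if len(structures) == 0:
            raise ValueError("model needs at least one structure")
        b = [np.asarray(m, dtype=float) for m in b_mats]
        if len(b) != len(structures):
            raise ValueError("need one coefficient matrix per structure")
        for k, (st, m) in enumerate(zip(structures, b)):
            if m.shape != (2, 2):
                raise ValueError(f"coefficient matrix {k} is not 2x2")
            if not np.allclose(m, m.T):
                raise ValueError(f"coefficient matrix {k} is not symmetric")
            if np.linalg.eigvalsh(m).min() < -psd_tol:
                raise ValueError(
                    f"coefficient matrix of structure {k} ({st.family}, "
                    f"range {st.range_km} km) is not positive semidefinite"
                )
        self.structures = list(structures)
        self.b_mats = b
        self.converged = converged

    def sill(self, component: str = "11") -> float:
        """Total sill (including nugget) of one component."""
        a, b = _COMP_IDX[component]
        return float(sum(m[a, b] for m in self.b_mats))

    def variogram(self, component: str, h: np.ndarray) -> np.ndarray:
        a, b = _COMP_IDX[component]
        h = np.asarray(h, dtype=float)
        out = np.zeros_like(h)
        for st, m in zip(self.structures, self.b_mats):
            out = out + m[a, b] * st.unit_variogram(h)
        return out

    def covariance(self, component: str, h: np.ndarray) -> np.ndarray:
        """C_ab(h) = sum_k B_k[a,b] * rho_k(h); nugget only at h = 0 exactly."""
        a, b = _COMP_IDX[component]
        h = np.asarray(h, dtype=float)
        out = np.zeros_like(h)
        for st, m in zip(self.structures, self.b_mats):
            out = out + m[a, b] * st.unit_correlogram(h)
        return out

    def marginal(self, component: str = "11") -> "CoregionalizationModel":
        """Single-variable model for one direct component (coefficients on
        the diagonal, zero elsewhere)."""
        a, b = _COMP_IDX[component]
        mats = []
        for m in self.b_mats:
            out = np.zeros((2, 2))
            out[a, b] = m[a, b]
            mats.append(out)
        return CoregionalizationModel(self.structures, mats)

    def cross_correlation(self) -> float:
        """Implied sill-level correlation between the two variables."""
        s11, s22, s12 = (self.sill(c) for c in COMPONENTS)
        if s11 <= 0 or s22 <= 0:
            return 0.0
        return s12 / np.sqrt(s11 * s22)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "structures": [
                {"family": s.family, "range_km": s.range_km}
                for s in self.structures
            ],
            "b_mats": [m.tolist() for m in self.b_mats],
            "converged": self.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CoregionalizationModel":
        structures = [
            VariogramStructure(s["family"], s["range_km"])
            for s in d["structures"]
        ]
        return cls(structures, d["b_mats"], converged=d.get("converged", True))

    @classmethod
    def from_json(cls, path) -> "CoregionalizationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{s.family}(a={s.range_km:g})" for s in self.structures
        )
        return f"CoregionalizationModel([{parts}])"


@dataclass
class EmpiricalVariogram:
    """Binned empirical (cross-)semivariogram.

    ``kind`` is ``direct-z1``, ``direct-z2`` or ``cross``.  Only bins with at
    least one pair are kept; lags are strictly increasing bin centers.
    """

    lags: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    kind: str = "direct-z1"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.semivariance = np.asarray(self.semivariance, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if not (np.diff(self.lags) > 0).all():
            raise ValueError("lag centers must be strictly increasing")
        if (self.pair_counts < 1).any():
            raise ValueError("reported bins must contain at least one pair")
        if self.kind.startswith("direct") and (self.semivariance < 0).any():
            raise ValueError("direct semivariances must be nonnegative")


def _bin_pairs(
    locations: np.ndarray, lag_bins: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise distances and their bin index (-1 = outside all bins)."""
    d = pdist(np.asarray(locations, dtype=float))
    edges = np.asarray(lag_bins, dtype=float)
    idx = np.digitize(d, edges) - 1
    idx[(d < edges[0]) | (d >= edges[-1])] = -1
    return d, idx


def _binned_variogram(
    locations, cross_products: np.ndarray, lag_bins, kind: str
) -> EmpiricalVariogram:
    d, idx = _bin_pairs(locations, lag_bins)
    edges = np.asarray(lag_bins, dtype=float)
    nbins = len(edges) - 1
    lags, gamma, counts = [], [], []
    for b in range(nbins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        lags.append(d[sel].mean())
        gamma.append(cross_products[sel].sum() / (2.0 * n))
        counts.append(n)
    if not lags:
        raise ValueError("no point pairs fall in any lag bin")
    return EmpiricalVariogram(
        np.array(lags), np.array(gamma), np.array(counts), kind
    )


def empirical_variogram(
    locations, values, lag_bins, kind: str = "direct-z1"
) -> EmpiricalVariogram:
    """Matheron estimator: gamma(h) = sum over pairs (z_i - z_j)^2 / (2 N(h)).

    ``lag_bins`` are bin edges in km; bin centers reported as the mean pair
    distance within each bin; empty bins are omitted.
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(locations) < 2:
        raise ValueError("need at least 2 points")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if pdist(locations).max() == 0.0:
        raise ValueError("all points coincident: no nonzero lags")
    diff2 = pdist(values[:, None], metric="sqeuclidean")
    return _binned_variogram(locations, diff2, lag_bins, kind)


def empirical_cross_variogram(
    locations, z1_values, z2_values, lag_bins
) -> EmpiricalVariogram:
    """Cross estimator: gamma12(h) = sum (dz1_ij * dz2_ij) / (2 N(h)).

    Points with a missing (NaN) covariate value are dropped, so only complete
    collocated pairs enter the sums.
    """
    locations = np.asarray(locations, dtype=float)
    z1 = np.asarray(z1_values, dtype=float)
    z2 = np.asarray(z2_values, dtype=float)
    ok = np.isfinite(z1) & np.isfinite(z2)
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete (z1, z2) pairs")
    locations, z1, z2 = locations[ok], z1[ok], z2[ok]
    n = len(z1)
    iu, ju = np.triu_indices(n, k=1)
    prod = (z1[iu] - z1[ju]) * (z2[iu] - z2[ju])
    return _binned_variogram(locations, prod, lag_bins, "cross")


# ---------------------------------------------------------------------------
# model fitting


def _cressie_weights(emp: EmpiricalVariogram) -> np.ndarray:
    """WLS weights N(h)/h^2 (Cressie); guards h=0 never occurs (lags > 0)."""
    return emp.pair_counts / np.maximum(emp.lags, 1e-12) ** 2


def _wsse(emp: EmpiricalVariogram, fitted: np.ndarray) -> float:
    w = _cressie_weights(emp)
    return float(np.sum(w * (emp.semivariance - fitted) ** 2))


@dataclass
class FittedVariogram:
    """Single-variable fit: nugget + one continuous structure (or pure nugget)."""

    structures: list[VariogramStructure]
    sills: np.ndarray  # per-structure sill, aligned with structures
    wsse: float
    family: str = field(default="")

    def variogram(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        out = np.zeros_like(h)
        for st, s in zip(self.structures, self.sills):
            out = out + s * st.unit_variogram(h)
        return out

    @property
    def nugget(self) -> float:
        for st, s in zip(self.structures, self.sills):
            if st.family == "nugget":
                return float(s)
        return 0.0

    @property
    def sill(self) -> float:
        """Partial sill of the continuous structure."""
        for st, s in zip(self.structures, self.sills):
            if st.family != "nugget":
                return float(s)
        return 0.0

    @property
    def range_km(self) -> float:
        for st in self.structures:
            if st.family != "nugget":
                return st.range_km
        return 0.0


def fit_variogram_model(
    empirical: EmpiricalVariogram,
    families: tuple[str, ...] = ("spherical", "exponential", "gaussian"),
) -> FittedVariogram:
    """Cressie-weighted WLS fit of nugget + one structure; best family by WSSE.

    A pure-nugget candidate is always included and preferred unless a
    continuous family strictly improves the weighted SSE.
    """
    emp = empirical
    if len(emp.lags) < 3:
        raise ValueError("need at least 3 nonempty lag bins to fit")
    w = np.sqrt(_cressie_weights(emp))
    gmax = max(emp.semivariance.max(), 1e-12)
    hmax = emp.lags.max()

    # pure-nugget candidate: weighted mean level
    level = np.sum(w**2 * emp.semivariance) / np.sum(w**2)
    level = max(level, 0.0)
    best = FittedVariogram(
        [VariogramStructure("nugget")],
        np.array([level]),
        _wsse(emp, np.full_like(emp.lags, level)),
        family="nugget",
    )

    failures = []
    for fam in families:
        def resid(p, fam=fam):
            nug, sill, rng = p
            fitted = nug + sill * _unit_variogram(fam, emp.lags, rng)
            return w * (fitted - emp.semivariance)

        x0 = np.array([0.1 * gmax, 0.9 * gmax, hmax / 3.0])
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=([0.0, 0.0, 1e-6], [2 * gmax, 4 * gmax, 10 * hmax]),
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            failures.append(f"{fam}: {exc}")
            continue
        nug, sill, rng = sol.x
        structures = [
            VariogramStructure("nugget"),
            VariogramStructure(fam, rng),
        ]
        cand = FittedVariogram(
            structures,
            np.array([nug, sill]),
            _wsse(emp, nug + sill * _unit_variogram(fam, emp.lags, rng)),
            family=fam,
        )
        if cand.wsse < best.wsse * (1.0 - 1e-9):
            best = cand
    if best is None:  # pragma: no cover
        raise RuntimeError("all variogram fits failed: " + "; ".join(failures))
    return best


def _project_psd(m: np.ndarray) -> np.ndarray:
    """Nearest PSD matrix in Frobenius norm: clip negative eigenvalues at 0."""
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def fit_lmc(
    direct_z1: EmpiricalVariogram,
    direct_z2: EmpiricalVariogram,
    cross: EmpiricalVariogram,
    structures: list[VariogramStructure],
    *,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> CoregionalizationModel:
    """Fit per-structure coefficient matrices by Goulard–Voltz descent.

    All three empirical components share the structure set (families and
    ranges fixed in advance, normally from the marginal fit of the primary
    variable).  Each sweep updates one coefficient matrix at a time by
    component-wise weighted least squares on the residual variogram, then
    projects it to the nearest PSD matrix, which guarantees the returned
    model is valid.  Non-convergence returns the best iterate flagged via
    ``converged=False``.
    """
    emps = {"11": direct_z1, "22": direct_z2, "12": cross}
    K = len(structures)
    # design columns g_k(h) and weights per component
    G = {c: np.stack([st.unit_variogram(emps[c].lags) for st in structures])
         for c in COMPONENTS}
    W = {c: _cressie_weights(emps[c]) for c in COMPONENTS}
    Y = {c: emps[c].semivariance for c in COMPONENTS}

    B = [np.zeros((2, 2)) for _ in range(K)]
    prev = None
    converged = False
    for _ in range(max_iter):
        for k in range(K):
            newmat = np.zeros((2, 2))
            for c in COMPONENTS:
                a, b = _COMP_IDX[c]
                others = sum(
                    B[l][a, b] * G[c][l] for l in range(K) if l != k
                )
                resid = Y[c] - others
                gk = G[c][k]
                denom = np.sum(W[c] * gk * gk)
                coef = np.sum(W[c] * gk * resid) / denom if denom > 0 else 0.0
                newmat[a, b] = coef
                newmat[b, a] = coef
            B[k] = _project_psd(newmat)
        flat = np.concatenate([m.ravel() for m in B])
        if prev is not None and np.max(np.abs(flat - prev)) < tol:
            converged = True
            break
        prev = flat
    return CoregionalizationModel(structures, B, converged=converged)


def fit_lmc_from_empirical(
    direct_z1: EmpiricalVariogram,
    direct_z2: EmpiricalVariogram,
    cross: EmpiricalVariogram,
) -> CoregionalizationModel:
    """Convenience: choose structures from the primary marginal fit, then
    fit the full LMC (the per-day model path of the pipeline)."""
    marg = fit_variogram_model(direct_z1)
    structures = list(marg.structures)
    if not any(s.family == "nugget" for s in structures):
        structures.insert(0, VariogramStructure("nugget"))
    return fit_lmc(direct_z1, direct_z2, cross, structures)
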