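"""Binding, kinetics and zinc-stoichiometry analysis.

Fits tryptophan-fluorescence titrations with the exact (ligand-depletion
aware) 1:1 binding model, Michaelis-Menten glutamylation kinetics, and
PAR/MMTS zinc-release calibrations, and derives the downstream
quantities: catalytic efficiency kcat/Km, fold changes between enzyme
variants, and binding free-energy differences ddG = RT ln(Kd_v/Kd_ref).

The 1:1 model uses the closed-form bound fraction

    f(L) = ((E + L + Kd) - sqrt((E + L + Kd)^2 - 4 E L)) / (2 E)

so titrations where enzyme and ligand concentrations are comparable
(e.g. 0.5 uM enzyme vs a ~60 nM Kd) are fitted without the
free-ligand ~ total-ligand approximation; the hyperbolic (Langmuir)
model is available for the L >> E regime.  Fits are bounded
trust-region least squares with a deterministic coarse log-grid
initialisation over the dissociation/Michaelis constant, so no random
seed is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE_K",
    "TitrationSeries",
    "KineticsSeries",
    "ZincAssay",
    "FitResult",
    "binding_signal",
    "binding_signal_hyperbolic",
    "fit_binding",
    "mm_rate",
    "fit_mm",
    "efficiency",
    "fold_change",
    "round_sig",
    "delta_g",
    "zinc_ratio",
]

#: gas constant in kcal mol^-1 K^-1 (1 cal == 4.184 J)
GAS_CONSTANT_KCAL = 1.987e-3
#: titration temperature, 25 C
STANDARD_TEMPERATURE_K = 298.15


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


def _as_increasing(name, values):
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 4:
        raise ValueError(f"{name}: need at least 4 points")
    if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
        raise ValueError(f"{name}: concentrations must be >= 0 and strictly increasing")
    return arr


@dataclass
class TitrationSeries:
    """One fluorescence titration: signal vs total ligand at fixed enzyme."""

    enzyme_conc: float  # M
    ligand_concs: np.ndarray  # M, strictly increasing
    signal: np.ndarray  # arbitrary units
    ligand_name: str = ""

    def __post_init__(self):
        self.ligand_concs = _as_increasing("ligand_concs", self.ligand_concs)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != self.ligand_concs.shape:
            raise ValueError("ligand_concs and signal lengths differ")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")


@dataclass
class KineticsSeries:
    """Initial-rate series: v vs substrate at fixed enzyme."""

    enzyme_conc: float  # M
    substrate_concs: np.ndarray  # M
    rates: np.ndarray  # M s^-1

    def __post_init__(self):
        self.substrate_concs = _as_increasing("substrate_concs", self.substrate_concs)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != self.substrate_concs.shape:
            raise ValueError("substrate_concs and rates lengths differ")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")


@dataclass
class ZincAssay:
    """PAR/MMTS zinc-release assay: A500 standards plus one sample."""

    standards: list  # (zn_conc M, a500) pairs, >= 2
    sample_a500_background: float
    sample_a500_plateau: float
    protein_conc: float  # M

    def __post_init__(self):
        if len(self.standards) < 2:
            raise ValueError("need at least 2 standards")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive")


@dataclass
class FitResult:
    params: dict
    stderr: dict
    rmse: float
    n_points: int
    model: str
    covariance: np.ndarray = field(repr=False, default=None)


def binding_signal(L, E, kd, amplitude, baseline):
    """Exact 1:1 signal model with ligand depletion (quadratic root)."""
    L = np.asarray(L, dtype=float)
    s = E + L + kd
    bound = (s - np.sqrt(np.maximum(s * s - 4.0 * E * L, 0.0))) / (2.0 * E)
    return baseline + amplitude * bound


def binding_signal_hyperbolic(L, E, kd, amplitude, baseline):
    """Langmuir approximation (free ligand ~ total ligand)."""
    L = np.asarray(L, dtype=float)
    return baseline + amplitude * L / (kd + L)


def _ls_fit(residual_fn, x0, bounds, param_names, n_points, model, y_scale=1.0):
    # residuals are normalised to O(1) so the gradient-norm stopping rule
    # is meaningful whatever the data units (rates may be ~1e-8 M/s);
    # the parameter covariance is invariant to this scaling
    scaled = lambda p: residual_fn(p) / y_scale
    x_scale = [abs(x) if x != 0 else 1.0 for x in x0]
    res = least_squares(
        scaled, x0, bounds=bounds, method="trf",
        x_scale=x_scale, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitError(f"{model} fit did not converge (residual norm {np.linalg.norm(res.fun):.3g})")
    dof = max(n_points - len(x0), 1)
    sigma2 = float(res.fun @ res.fun) / dof
    try:
        cov = sigma2 * np.linalg.inv(res.jac.T @ res.jac)
        stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((len(x0), len(x0)), np.nan)
        stderr = np.full(len(x0), np.nan)
    return FitResult(
        params=dict(zip(param_names, res.x)),
        stderr=dict(zip(param_names, stderr)),
        rmse=float(np.sqrt(np.mean(res.fun**2))) * y_scale,
        n_points=n_points,
        model=model,
        covariance=cov,
    )


def fit_binding(series: TitrationSeries, model: str = "quadratic") -> FitResult:
    """Fit Kd, amplitude and baseline to a 1:1 titration.

    ``model`` is ``"quadratic"`` (depletion-aware, default) or
    ``"hyperbolic"``.  Kd is bounded below by 0; initialisation scans a
    coarse log grid of Kd with the amplitude/baseline solved linearly at
    each grid point, then refines by trust-region least squares.
    """
    fn = binding_signal if model == "quadratic" else binding_signal_hyperbolic
    L, y, E = series.ligand_concs, series.signal, series.enzyme_conc
    lmax = max(L.max(), E)
    grid = np.geomspace(lmax * 1e-5, lmax * 1e2, 36)
    best = None
    for kd0 in grid:
        f = fn(L, E, kd0, 1.0, 0.0)
        A = np.column_stack([f, np.ones_like(f)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = A @ coef - y
        sse = float(r @ r)
        if best is None or sse < best[0]:
            best = (sse, kd0, coef[0], coef[1])
    _, kd0, amp0, base0 = best

    def resid(p):
        return fn(L, E, p[0], p[1], p[2]) - y

    return _ls_fit(
        resid,
        x0=[kd0, amp0, base0],
        bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        param_names=["kd", "amplitude", "baseline"],
        n_points=L.size,
        model=f"binding-{model}",
        y_scale=float(np.max(np.abs(y))) or 1.0,
    )


def mm_rate(S, E, kcat, km):
    S = np.asarray(S, dtype=float)
    return kcat * E * S / (km + S)


def fit_mm(series: KineticsSeries) -> FitResult:
    """Fit kcat and Km to an initial-rate Michaelis-Menten series."""
    S, v, E = series.substrate_concs, series.rates, series.enzyme_conc
    grid = np.geomspace(S.min() * 1e-2, S.max() * 1e2, 36)
    best = None
    for km0 in grid:
        f = S / (km0 + S)
        denom = float(f @ f)
        vmax0 = float(f @ v) / denom if denom > 0 else 0.0
        r = vmax0 * f - v
        sse = float(r @ r)
        if best is None or sse < best[0]:
            best = (sse, km0, vmax0)
    _, km0, vmax0 = best

    def resid(p):
        return mm_rate(S, E, p[0], p[1]) - v

    return _ls_fit(
        resid,
        x0=[max(vmax0 / E, 1e-12), km0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        param_names=["kcat", "km"],
        n_points=S.size,
        model="michaelis-menten",
        y_scale=float(np.max(np.abs(v))) or 1.0,
    )


def efficiency(kcat: float, km: float) -> float:
    """Catalytic efficiency kcat/Km in M^-1 s^-1 (km in M)."""
    if km <= 0:
        raise ValueError("km must be positive")
    return kcat / km


def round_sig(x: float, sig_figs: int) -> float:
    """Round to significant figures (round-half-even, like printing)."""
    if x == 0:
        return 0.0
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    ndigits = sig_figs - 1 - math.floor(math.log10(abs(x)))
    return round(x, ndigits)


def fold_change(reference: float, variant: float, sig_figs: int = 2, direction: str = "ref/var") -> float:
    """Ratio between a reference and a variant value, rounded to
    ``sig_figs`` significant figures.  ``direction`` is ``"ref/var"``
    (default; e.g. activity loss) or ``"var/ref"`` (e.g. Km increase)."""
    if reference <= 0 or variant <= 0:
        raise ValueError("fold change requires positive values")
    ratio = reference / variant if direction == "ref/var" else variant / reference
    return round_sig(ratio, sig_figs)


def delta_g(
    kd_ref: float,
    kd_variant: float,
    temperature: float = STANDARD_TEMPERATURE_K,
) -> float:
    """Binding free-energy difference ddG = RT ln(Kd_variant / Kd_ref).

    Positive when the variant binds more weakly (unfavourable), in
    kcal/mol with R = 1.987e-3 kcal mol^-1 K^-1.
    """
    if kd_ref <= 0 or kd_variant <= 0 or temperature <= 0:
        raise ValueError("Kd values and temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd_variant / kd_ref)


def zinc_ratio(assay: ZincAssay, allow_extrapolation: bool = True):
    """Zn:protein molar ratio from a PAR absorbance calibration.

    A straight line is fitted through the standards (least squares); the
    sample's background-subtracted A500 is inverse-predicted to a zinc
    concentration and divided by the protein concentration.  Returns
    ``(ratio, extrapolated)`` where ``extrapolated`` flags a sample
    outside the standards' absorbance range (a warning is emitted; pass
    ``allow_extrapolation=False`` to make it an error).
    """
    import warnings

    zn = np.array([s[0] for s in assay.standards], dtype=float)
    a = np.array([s[1] for s in assay.standards], dtype=float)
    if np.allclose(zn, zn[0]):
        raise ValueError("singular calibration: standards span no concentration range")
    slope, intercept = np.polyfit(zn, a, 1)
    if slope == 0:
        raise ValueError("singular calibration: zero slope")
    delta = assay.sample_a500_plateau - assay.sample_a500_background
    zn_conc = (delta - intercept) / slope  # inverse prediction
    lo, hi = float(a.min()), float(a.max())
    extrapolated = not (lo <= delta <= hi)
    if extrapolated:
        msg = f"sample dA500={delta:.3g} outside standard range [{lo:.3g}, {hi:.3g}]"
        if not allow_extrapolation:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return zn_conc / assay.protein_conc, extrapolated
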