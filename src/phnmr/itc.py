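"""Single-site ITC binding: isotherm simulation and least-squares fitting.

The one-site (Wiseman) model treats each injection as re-equilibrating
macromolecule M and ligand X in the cell at their post-injection total
concentrations; the bound fraction follows the quadratic solution of the
binding equilibrium, and the cumulative heat is

    Q_i = n * theta_i * [M]_i * dH * V0,

with the per-injection observed heat corrected for the liquid displaced
from a constant-volume cell:

    dq_i = Q_i - Q_{i-1} + (dV_i / V0) * (Q_i + Q_{i-1}) / 2 + q_offset.

Dilution of both species by the injected volume is tracked exactly
(perfusion model). Fitting follows the statsmodels convention: build a
:class:`OneSiteBindingModel` from an :class:`ITCExperiment` carrying
measured heats, call :meth:`~OneSiteBindingModel.fit`, and read estimates,
standard errors and derived thermodynamics off the returned
:class:`OneSiteFitResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from phnmr.exceptions import ParameterError

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.9872e-3

#: Default temperature: 20 C.
DEFAULT_TEMPERATURE_K = 293.15

KCAL_TO_UCAL = 1e9


@dataclass(frozen=True)
class ITCExperiment:
    """An ITC titration design, optionally with measured injection heats.

    Concentrations in µM, cell volume in ml, injection volumes in µl,
    heats in µcal per injection.
    """

    cell_volume_ml: float = 2.0
    cell_conc_uM: float = 30.0
    syringe_conc_uM: float = 300.0
    injection_volumes_ul: tuple = tuple([20.0] * 25)
    temperature_K: float = DEFAULT_TEMPERATURE_K
    spacing_s: float = 210.0
    injection_duration_s: float = 4.0
    heats_ucal: tuple | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "injection_volumes_ul",
            tuple(float(v) for v in self.injection_volumes_ul),
        )
        if self.cell_volume_ml <= 0 or self.cell_conc_uM <= 0:
            raise ValueError("cell volume and concentration must be > 0")
        if self.syringe_conc_uM < 0:
            raise ValueError("syringe concentration must be >= 0")
        if any(v <= 0 for v in self.injection_volumes_ul):
            raise ValueError("injection volumes must be > 0")
        if self.heats_ucal is not None:
            heats = tuple(float(q) for q in self.heats_ucal)
            if len(heats) != len(self.injection_volumes_ul):
                raise ValueError("heats list must match number of injections")
            object.__setattr__(self, "heats_ucal", heats)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)

    def with_heats(self, heats) -> "ITCExperiment":
        return replace(self, heats_ucal=tuple(float(q) for q in heats))

    def molar_ratios(self) -> np.ndarray:
        """Post-injection ligand:macromolecule total-concentration ratios."""
        mt, xt, _ = _cell_concentrations(self)
        return xt / mt


@dataclass(frozen=True)
class BindingParams:
    """One-site model parameters: stoichiometry n, association constant Ka
    (1/M), enthalpy dH (kcal/mol), and a per-injection heat offset (µcal)
    absorbing heats of dilution."""

    n: float = 1.0
    ka: float = 1e7
    dh: float = -10.0
    q_offset: float = 0.0

    def __post_init__(self):
        if self.ka <= 0:
            raise ParameterError(f"ka must be > 0, got {self.ka}")
        if self.n <= 0:
            raise ParameterError(f"n must be > 0, got {self.n}")

    @property
    def kd_nM(self) -> float:
        return 1e9 / self.ka


def thermodynamics(ka: float, dh: float, temperature: float = DEFAULT_TEMPERATURE_K):
    """Derived (dG, TdS) in kcal/mol from Ka (1/M) and dH (kcal/mol).

    dG = -R*T*ln(Ka); TdS = dH - dG (from dG = dH - TdS).
    """
    if ka <= 0 or temperature <= 0:
        raise ParameterError("ka and temperature must be > 0")
    dg = -R_KCAL * temperature * math.log(ka)
    return dg, dh - dg


def _cell_concentrations(exp: ITCExperiment):
    """Total concentrations (M) of macromolecule and ligand in the cell
    after each injection, under the constant-volume perfusion model.

    Material injected mixes into the cell while an equal volume of the
    current mixture is displaced; to the standard first-order treatment
    the totals after cumulative injected volume dV are
    M_t = M0 (1 - dV/2V0)/(1 + dV/2V0) and
    X_t = X0 (dV/V0)/(1 + dV/2V0).
    """
    v0 = exp.cell_volume_ml * 1e-3            # L
    dv = np.cumsum(exp.injection_volumes_ul) * 1e-6  # L
    m0 = exp.cell_conc_uM * 1e-6              # M
    x0 = exp.syringe_conc_uM * 1e-6           # M
    frac = dv / v0
    mt = m0 * (1 - frac / 2) / (1 + frac / 2)
    xt = x0 * frac / (1 + frac / 2)
    return mt, xt, v0


def _bound_fraction(mt, xt, n, ka):
    """Fraction of macromolecule sites occupied, from the binding quadratic.

    theta^2 - theta (1 + X/(nM) + 1/(n Ka M)) + X/(nM) = 0, smaller root.
    """
    r = xt / (n * mt)
    k = 1.0 / (n * ka * mt)
    b = 1.0 + r + k
    disc = np.maximum(b * b - 4.0 * r, 0.0)
    return (b - np.sqrt(disc)) / 2.0


def simulate_isotherm(exp: ITCExperiment, params: BindingParams) -> np.ndarray:
    """Per-injection heats (µcal) for a one-site binding experiment."""
    mt, xt, v0 = _cell_concentrations(exp)
    if exp.syringe_conc_uM == 0:
        return np.full(exp.n_injections, params.q_offset)
    theta = _bound_fraction(mt, xt, params.n, params.ka)
    q_cum = params.n * theta * mt * params.dh * v0 * KCAL_TO_UCAL  # µcal
    dv = np.asarray(exp.injection_volumes_ul) * 1e-6
    heats = np.empty(exp.n_injections)
    q_prev = 0.0
    for i in range(exp.n_injections):
        heats[i] = (
            q_cum[i] - q_prev
            + (dv[i] / v0) * (q_cum[i] + q_prev) / 2.0
            + params.q_offset
        )
        q_prev = q_cum[i]
    return heats


class OneSiteBindingModel:
    """One-site binding model for an ITC titration.

    Parameters
    ----------
    experiment : ITCExperiment
        The titration design together with measured heats (µcal).
    drop_first : bool
        Discard the first injection before fitting (common practice for
        diffusion artifacts at the syringe tip). Default False.
    """

    def __init__(self, experiment: ITCExperiment, drop_first: bool = False):
        if experiment.heats_ucal is None:
            raise ValueError("experiment must carry measured heats to fit")
        if experiment.n_injections - int(drop_first) < 5:
            raise ValueError("need at least 5 informative injections")
        self.experiment = experiment
        self.drop_first = drop_first
        self._mask = np.ones(experiment.n_injections, dtype=bool)
        if drop_first:
            self._mask[0] = False

    @classmethod
    def from_dataframe(cls, frame, cell_conc_uM, syringe_conc_uM,
                       cell_volume_ml=2.0, temperature_K=DEFAULT_TEMPERATURE_K,
                       drop_first=False):
        """Build from a DataFrame with columns volume_ul and heat_ucal."""
        exp = ITCExperiment(
            cell_volume_ml=cell_volume_ml,
            cell_conc_uM=cell_conc_uM,
            syringe_conc_uM=syringe_conc_uM,
            injection_volumes_ul=tuple(frame["volume_ul"]),
            temperature_K=temperature_K,
            heats_ucal=tuple(frame["heat_ucal"]),
        )
        return cls(exp, drop_first=drop_first)

    # -- internals ---------------------------------------------------------

    def _design_response(self, n: float, ka: float) -> np.ndarray:
        """Heats for dh=1, q_offset=0: the model is linear in (dh, offset)."""
        params = BindingParams(n=n, ka=ka, dh=1.0, q_offset=0.0)
        return simulate_isotherm(self.experiment, params)

    def _coarse_start(self) -> BindingParams:
        """Grid over log10 Ka with n = 1, solving (dh, offset) linearly."""
        y = np.asarray(self.experiment.heats_ucal)[self._mask]
        best = None
        for log_ka in np.arange(3.0, 12.01, 0.25):
            a = self._design_response(1.0, 10.0**log_ka)[self._mask]
            design = np.column_stack([a, np.ones_like(a)])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            sse = float(resid @ resid)
            if best is None or sse < best[0]:
                best = (sse, log_ka, coef[0], coef[1])
        _, log_ka, dh, off = best
        if abs(dh) < 1e-12:
            dh = -1e-6  # degenerate (all-zero) data; keep parameters legal
        return BindingParams(n=1.0, ka=10.0**log_ka, dh=dh, q_offset=off)

    def fit(self) -> "OneSiteFitResult":
        """Least-squares fit of (n, Ka, dH, q_offset) to the heats."""
        y = np.asarray(self.experiment.heats_ucal)
        start = self._coarse_start()
        pars = lmfit.Parameters()
        pars.add("n", value=start.n, min=0.05, max=10.0)
        pars.add("log10_ka", value=math.log10(start.ka), min=1.0, max=14.0)
        pars.add("dh", value=start.dh)
        pars.add("q_offset", value=start.q_offset)
        mask = self._mask

        def residual(p):
            params = BindingParams(
                n=p["n"].value, ka=10.0 ** p["log10_ka"].value,
                dh=p["dh"].value, q_offset=p["q_offset"].value,
            )
            return (simulate_isotherm(self.experiment, params) - y)[mask]

        minres = lmfit.minimize(residual, pars, method="leastsq",
                                xtol=1e-12, ftol=1e-12)
        p = minres.params
        params = BindingParams(
            n=p["n"].value, ka=10.0 ** p["log10_ka"].value,
            dh=p["dh"].value, q_offset=p["q_offset"].value,
        )
        stderr = {}
        for name in ("n", "log10_ka", "dh", "q_offset"):
            stderr[name] = p[name].stderr if p[name].stderr is not None else float("nan")
        # delta method: sd(Kd)/Kd = ln(10) * sd(log10 Ka)
        kd = params.kd_nM
        kd_stderr = abs(kd * math.log(10.0) * stderr["log10_ka"])
        dg, tds = thermodynamics(params.ka, params.dh, self.experiment.temperature_K)
        c_value = params.ka * self.experiment.cell_conc_uM * 1e-6 * params.n
        return OneSiteFitResult(
            model=self,
            params=params,
            kd_nM=kd,
            dg_kcal=dg,
            tds_kcal=tds,
            stderr=stderr,
            kd_stderr_nM=kd_stderr,
            rss=float(np.sum(np.asarray(minres.residual) ** 2)),
            converged=bool(minres.success),
            c_value=c_value,
            n_obs=int(mask.sum()),
        )


@dataclass(frozen=True)
class OneSiteFitResult:
    """Estimates, uncertainties and diagnostics of a one-site ITC fit."""

    model: OneSiteBindingModel
    params: BindingParams
    kd_nM: float
    dg_kcal: float
    tds_kcal: float
    stderr: dict
    kd_stderr_nM: float
    rss: float
    converged: bool
    c_value: float
    n_obs: int

    @property
    def c_value_ok(self) -> bool:
        """Kd is well determined for c roughly in 1..1e4."""
        return 1.0 <= self.c_value <= 1e4

    def fitted_heats(self) -> np.ndarray:
        return simulate_isotherm(self.model.experiment, self.params)

    def residuals(self) -> np.ndarray:
        return np.asarray(self.model.experiment.heats_ucal) - self.fitted_heats()

    def summary(self) -> str:
        p = self.params
        exp = self.model.experiment
        lines = [
            "One-site ITC binding fit",
            "=" * 48,
            f"Injections used:     {self.n_obs} of {exp.n_injections}",
            f"Temperature:         {exp.temperature_K:.2f} K",
            f"Cell / syringe:      {exp.cell_conc_uM:g} uM / {exp.syringe_conc_uM:g} uM",
            "-" * 48,
            f"n (sites):           {p.n:10.4f}  +/- {self.stderr['n']:.4f}",
            f"Ka (1/M):            {p.ka:10.4g}",
            f"Kd (nM):             {self.kd_nM:10.2f}  +/- {self.kd_stderr_nM:.2f}",
            f"dH (kcal/mol):       {p.dh:10.3f}  +/- {self.stderr['dh']:.3f}",
            f"q offset (ucal):     {p.q_offset:10.4f}  +/- {self.stderr['q_offset']:.4f}",
            f"dG (kcal/mol):       {self.dg_kcal:10.3f}",
            f"TdS (kcal/mol):      {self.tds_kcal:10.3f}",
            "-" * 48,
            f"RSS (ucal^2):        {self.rss:10.4g}",
            f"c value:             {self.c_value:10.3g}"
            + ("" if self.c_value_ok else "  [warning: Kd poorly determined]"),
            f"Converged:           {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured vs fitted heats against molar ratio (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        ratios = self.model.experiment.molar_ratios()
        ax.plot(ratios, self.model.experiment.heats_ucal, "o", label="measured")
        ax.plot(ratios, self.fitted_heats(), "-", label="one-site fit")
        ax.set_xlabel("molar ratio X/M")
        ax.set_ylabel("heat per injection (ucal)")
        ax.legend()
        return ax


def fit_single_site(exp: ITCExperiment, drop_first: bool = False) -> OneSiteFitResult:
    """Convenience wrapper: fit the one-site model to an experiment."""
    return OneSiteBindingModel(exp, drop_first=drop_first).fit()
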