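"""Host-guest speciation and global multiwavelength titration fitting.

The equilibrium system is a set of complexes H_hG_g governed by cumulative
formation constants beta_hg,

    [H_hG_g] = beta_hg [H]^h [G]^g,       beta parameterized as log10,

closed by the two mass balances

    h_tot = [H] + sum_s h_s [s],      g_tot = [G] + sum_s g_s [s].

:func:`solve_speciation` solves these by damped Newton iteration in
log-concentration space (positivity is automatic).  :class:`TitrationModel`
fits an absorbance matrix A(point, wavelength) globally over all wavelengths
by variable projection: the outer search runs over the log beta values while
the molar absorptivity spectrum of each absorbing species is obtained at
every step by non-negative linear least squares, exactly the structure of
the classical multiwavelength titration programs.  Model adequacy is judged
by the distribution of residuals (runs tests down the titration at each
wavelength) and candidate stoichiometries are ranked by trend verdict first
and small-sample AIC second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls
from scipy.stats import norm

from .exceptions import DomainError, NumericalError, ValidationError

__all__ = [
    "Species",
    "BindingModel",
    "TitrationData",
    "SpeciationState",
    "solve_speciation",
    "speciation_matrix",
    "predict_absorbance",
    "TitrationModel",
    "TitrationResults",
    "fit_titration",
    "residual_trend_test",
    "TrendReport",
    "select_model",
    "ModelSelectionReport",
]

FREE_GUEST = (0, 1)


@dataclass(frozen=True)
class Species:
    """A complex H_hG_g with its log10 cumulative formation constant."""

    h: int
    g: int
    log_beta: float

    def __post_init__(self):
        if self.h < 0 or self.g < 0 or self.h + self.g < 2:
            raise ValidationError(f"invalid complex stoichiometry ({self.h},{self.g})")

    @property
    def key(self):
        return (self.h, self.g)

    @property
    def name(self):
        return f"{self.h}:{self.g}"


class BindingModel:
    """A set of host-guest complexes defining the equilibrium system.

    The free guest (0,1) with log beta = 0 is implicit and always present;
    the free host likewise.  ``absorbing`` lists the (h, g) keys whose
    species contribute absorbance; by default that is the free guest plus
    every complex containing guest (the cyclodextrin host is transparent in
    the near UV).
    """

    def __init__(self, species, absorbing=None):
        sp = []
        for s in species:
            if not isinstance(s, Species):
                s = Species(*s)
            sp.append(s)
        keys = [s.key for s in sp]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (h, g) species")
        if not any(s.h >= 1 and s.g >= 1 for s in sp):
            raise ValidationError("need at least one mixed host-guest complex")
        self.species = tuple(sp)
        if absorbing is None:
            absorbing = [FREE_GUEST] + [s.key for s in sp if s.g >= 1]
        self.absorbing = tuple(absorbing)

    @property
    def name(self) -> str:
        return "+".join(s.name for s in self.species)

    @classmethod
    def from_name(cls, name: str, log_betas=None) -> "BindingModel":
        """Build from a stoichiometry string such as ``"1:1"`` or ``"1:1+1:2"``.

        ``log_betas`` gives one starting log10 beta per listed complex
        (default 3.0 each).
        """
        parts = [p.strip() for p in name.split("+")]
        if log_betas is None:
            log_betas = [3.0] * len(parts)
        if len(log_betas) != len(parts):
            raise ValidationError("one log_beta per species required")
        sp = []
        for part, lb in zip(parts, log_betas):
            h, g = part.split(":")
            sp.append(Species(int(h), int(g), float(lb)))
        return cls(sp)

    def with_log_betas(self, log_betas) -> "BindingModel":
        sp = [Species(s.h, s.g, float(lb)) for s, lb in zip(self.species, log_betas)]
        return BindingModel(sp, absorbing=self.absorbing)

    def __repr__(self):
        inner = ", ".join(f"{s.name}: logB={s.log_beta:.3f}" for s in self.species)
        return f"BindingModel({inner})"


@dataclass(frozen=True)
class SpeciationState:
    """Free and complex concentrations at one titration point (all M)."""

    free_h: float
    free_g: float
    conc: dict  # (h, g) -> M for each complex

    def total_h(self) -> float:
        return self.free_h + sum(h * c for (h, _), c in self.conc.items())

    def total_g(self) -> float:
        return self.free_g + sum(g * c for (_, g), c in self.conc.items())

    def bound_guest_fraction(self) -> float:
        tg = self.total_g()
        if tg <= 0:
            raise DomainError("no guest present")
        return 1.0 - self.free_g / tg


def solve_speciation(model: BindingModel, h_tot: float, g_tot: float,
                     tol: float = 1e-12, max_iter: int = 200) -> SpeciationState:
    """Solve the two mass balances for the free concentrations.

    Newton iteration on (ln[H], ln[G]) with step damping; converged when both
    scaled mass-balance residuals fall below ``tol`` (relative).
    """
    if h_tot < 0 or g_tot < 0:
        raise ValidationError("totals must be non-negative")
    if not 0 < tol <= 1e-6:
        raise ValidationError("tol must be in (0, 1e-6]")

    hs = np.array([s.h for s in model.species], dtype=float)
    gs = np.array([s.g for s in model.species], dtype=float)
    betas = np.array([10.0 ** s.log_beta if np.isfinite(s.log_beta) else 0.0
                      for s in model.species])

    # components with zero total are absent; complexes needing them vanish
    active_h = h_tot > 0
    active_g = g_tot > 0
    alive = np.ones(len(model.species), dtype=bool)
    if not active_h:
        alive &= hs == 0
    if not active_g:
        alive &= gs == 0

    def complex_conc(lnH, lnG):
        with np.errstate(over="ignore"):
            c = betas * np.exp(hs * lnH + gs * lnG)
        c = np.where(alive, c, 0.0)
        return c

    if not active_h and not active_g:
        return SpeciationState(0.0, 0.0, {s.key: 0.0 for s in model.species})

    lnH = math.log(h_tot) if active_h else -math.inf
    lnG = math.log(g_tot) if active_g else -math.inf
    scale_h = h_tot if active_h else 1.0
    scale_g = g_tot if active_g else 1.0

    def residual(lnH, lnG):
        c = complex_conc(lnH if active_h else -math.inf,
                         lnG if active_g else -math.inf)
        H = math.exp(lnH) if active_h else 0.0
        G = math.exp(lnG) if active_g else 0.0
        fh = (H + float(hs @ c) - h_tot) / scale_h
        fg = (G + float(gs @ c) - g_tot) / scale_g
        return fh, fg, H, G, c

    fh, fg, H, G, c = residual(lnH, lnG)
    for _ in range(max_iter):
        err = max(abs(fh) if active_h else 0.0, abs(fg) if active_g else 0.0)
        if err <= tol:
            break
        # Jacobian of the totals w.r.t. log free concentrations
        jhh = (H + float(hs * hs @ c)) / scale_h
        jhg = float(hs * gs @ c)
        jgg = (G + float(gs * gs @ c)) / scale_g
        if active_h and active_g:
            J = np.array([[jhh, jhg / scale_h], [jhg / scale_g, jgg]])
            try:
                step = np.linalg.solve(J, np.array([fh, fg]))
            except np.linalg.LinAlgError as exc:
                raise NumericalError(f"singular Jacobian at residual {err:.2e}") from exc
            dH, dG = step
        elif active_h:
            dH, dG = fh / jhh, 0.0
        else:
            dH, dG = 0.0, fg / jgg
        # cap and damp the step so exp() stays finite and residual decreases
        m = max(abs(dH), abs(dG))
        if m > 5.0:
            dH, dG = dH * 5.0 / m, dG * 5.0 / m
        lam = 1.0
        base = max(abs(fh), abs(fg))
        for _ in range(40):
            nfh, nfg, nH, nG, nc = residual(lnH - lam * dH, lnG - lam * dG)
            if max(abs(nfh), abs(nfg)) < base:
                break
            lam *= 0.5
        lnH, lnG = lnH - lam * dH, lnG - lam * dG
        fh, fg, H, G, c = nfh, nfg, nH, nG, nc
    else:
        raise NumericalError(
            f"speciation did not converge; last scaled residual {max(abs(fh), abs(fg)):.2e}"
        )
    return SpeciationState(H, G, {s.key: float(ci) for s, ci in zip(model.species, c)})


def speciation_matrix(model: BindingModel, h_tots, g_tot: float,
                      tol: float = 1e-12) -> np.ndarray:
    """(n_points, n_absorbing) concentration matrix in model.absorbing order."""
    rows = []
    for h in np.asarray(h_tots, dtype=float):
        st = solve_speciation(model, float(h), g_tot, tol=tol)
        lookup = dict(st.conc)
        lookup[FREE_GUEST] = st.free_g
        lookup[(1, 0)] = st.free_h
        rows.append([lookup[k] for k in model.absorbing])
    return np.asarray(rows)


@dataclass(frozen=True)
class TitrationData:
    """A multiwavelength titration: constant guest, varied host.

    ``absorbance`` has one row per host level and one column per wavelength.
    The host grid must contain the guest-only reference (h_tot = 0).
    """

    g_tot: float
    h_tot: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray
    path_length: float = 1.0

    def __post_init__(self):
        h = np.asarray(self.h_tot, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if self.g_tot <= 0:
            raise ValidationError("g_tot must be positive")
        if np.any(h < 0):
            raise ValidationError("h_tot must be non-negative")
        if 0.0 not in h:
            raise ValidationError("h_tot must include the guest-only reference (0 M)")
        if a.shape != (h.size, wl.size):
            raise ValidationError(
                f"absorbance shape {a.shape} != (n_points={h.size}, n_wavelengths={wl.size})"
            )
        object.__setattr__(self, "h_tot", h)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", a)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, g_tot: float, path_length: float = 1.0):
        """First column ``h_tot_M``; remaining column headers are nm."""
        h = df["h_tot_M"].to_numpy(dtype=float)
        wl_cols = [c for c in df.columns if c != "h_tot_M"]
        wl = np.array([float(c) for c in wl_cols])
        return cls(g_tot, h, wl, df[wl_cols].to_numpy(dtype=float), path_length)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.absorbance, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "h_tot_M", self.h_tot)
        return df


def predict_absorbance(model: BindingModel, epsilon: dict, data: TitrationData) -> np.ndarray:
    """Beer-Lambert forward model A = path * C @ E.

    ``epsilon`` maps each absorbing (h, g) key to its molar absorptivity
    spectrum over ``data.wavelengths``.
    """
    try:
        E = np.vstack([np.asarray(epsilon[k], dtype=float) for k in model.absorbing])
    except KeyError as exc:
        raise ValidationError(f"missing epsilon for absorbing species {exc.args[0]}") from exc
    if E.shape[1] != data.wavelengths.size:
        raise ValidationError("epsilon length does not match the wavelength grid")
    C = speciation_matrix(model, data.h_tot, data.g_tot)
    return data.path_length * C @ E


# ---------------------------------------------------------------------------
# global fitting


class TitrationModel:
    """Global multiwavelength binding-constant fit by variable projection.

    The nonlinear parameters are the log10 cumulative constants of
    ``binding_model``; at each trial value the speciation is solved and the
    per-wavelength absorptivities follow from non-negative least squares, so
    the outer optimizer only ever sees the log beta axis.
    """

    def __init__(self, data: TitrationData, binding_model: BindingModel):
        self.data = data
        self.binding_model = binding_model
        n_p = len(binding_model.species)
        if data.h_tot.size < n_p + 2:
            raise ValidationError(
                "need at least two more titration points than free log beta parameters"
            )

    # -- variable projection core -------------------------------------------------
    def _project(self, log_betas):
        """Residual matrix and NNLS absorptivities at fixed log betas."""
        m = self.binding_model.with_log_betas(log_betas)
        C = self.data.path_length * speciation_matrix(m, self.data.h_tot, self.data.g_tot)
        A = self.data.absorbance
        n_wl = A.shape[1]
        E = np.empty((C.shape[1], n_wl))
        for j in range(n_wl):
            E[:, j], _ = nnls(C, A[:, j])
        resid = A - C @ E
        return resid, E

    def _residual_vector(self, log_betas):
        return self._project(log_betas)[0].ravel()

    def fit(self, starts: int = 7, seed: int = 0,
            bounds: tuple = (0.0, 8.0)) -> "TitrationResults":
        """Multistart bounded least squares over log beta.

        ``starts`` initial points are drawn from the [1, 6] log beta box
        (the first at its centre), the best converged solution is kept, and
        the standard errors come from the Gauss-Newton curvature of the
        projected problem.
        """
        if starts < 1:
            raise ValidationError("need at least one start")
        rng = np.random.default_rng(seed)
        p = len(self.binding_model.species)
        x0s = [np.full(p, 3.5)]
        x0s += [rng.uniform(1.0, 6.0, size=p) for _ in range(starts - 1)]
        best = None
        for x0 in x0s:
            try:
                res = least_squares(self._residual_vector, x0, bounds=bounds,
                                    method="trf", xtol=1e-12, ftol=1e-14, gtol=1e-12)
            except NumericalError:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise NumericalError("all multistart fits failed to converge")

        resid_mat, E = self._project(best.x)
        rss = float(np.sum(resid_mat ** 2))
        m = resid_mat.size
        n_lin = E.size
        dof = max(m - p - n_lin, 1)
        s2 = rss / dof
        JtJ = best.jac.T @ best.jac
        degenerate = False
        se = np.full(p, np.nan)
        scale = float(np.trace(JtJ)) / p if p else 0.0
        if scale <= 1e-12 * max(1.0, m):
            degenerate = True  # rss flat over the log beta span
        else:
            try:
                cov = s2 * np.linalg.inv(JtJ)
                diag = np.diag(cov)
                if np.any(diag < 0) or np.linalg.cond(JtJ) > 1e10:
                    degenerate = True
                else:
                    se = np.sqrt(diag)
            except np.linalg.LinAlgError:
                degenerate = True

        fitted_model = self.binding_model.with_log_betas(best.x)
        n_param = p + n_lin
        aicc = _aicc(m, n_param, rss)
        return TitrationResults(
            model=self,
            binding_model=fitted_model,
            log_beta=np.asarray(best.x, dtype=float),
            log_beta_se=se,
            epsilon={k: E[i].copy() for i, k in enumerate(fitted_model.absorbing)},
            rss=rss,
            residuals=resid_mat,
            aicc=aicc,
            degenerate=degenerate,
        )


def _aicc(n: int, k: int, rss: float) -> float:
    """Small-sample AIC for Gaussian residuals (variance profiled out)."""
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return aic


@dataclass(frozen=True)
class TrendReport:
    """Per-wavelength runs-test p-values and the aggregate verdict."""

    p_values: np.ndarray
    alpha: float
    fraction_rejecting: float
    systematic: bool

    def __bool__(self):
        return self.systematic


def residual_trend_test(fit_or_residuals, alpha: float = 0.05) -> TrendReport:
    """Wald-Wolfowitz runs tests on residual signs down the titration.

    For each wavelength the residual signs (zero counted positive) are
    tested for too *few* runs — the signature of a systematic, one-sided
    misfit — via the one-sided normal approximation.  The overall verdict is
    "systematic" when the fraction of wavelengths rejecting at ``alpha``
    exceeds ``alpha``, i.e. more than expected by chance.
    """
    if isinstance(fit_or_residuals, TitrationResults):
        return fit_or_residuals.trend(alpha=alpha)
    resid = np.asarray(fit_or_residuals, dtype=float)
    if resid.ndim != 2:
        raise ValidationError("residuals must be a (points x wavelengths) matrix")
    n_wl = resid.shape[1]
    p_values = np.empty(n_wl)
    for j in range(n_wl):
        signs = resid[:, j] >= 0  # tie rule: exact zeros count as positive
        n1 = int(signs.sum())
        n2 = signs.size - n1
        runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
        if n1 == 0 or n2 == 0:
            p_values[j] = 0.0  # single-signed residuals: maximal trend
            continue
        n = n1 + n2
        mu = 2.0 * n1 * n2 / n + 1.0
        var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
        if var <= 0:
            p_values[j] = 1.0
            continue
        z = (runs - mu) / math.sqrt(var)
        p_values[j] = float(norm.cdf(z))
    frac = float(np.mean(p_values < alpha))
    return TrendReport(p_values=p_values, alpha=alpha,
                       fraction_rejecting=frac, systematic=frac > alpha)


@dataclass(frozen=True)
class TitrationResults:
    """Fitted constants, absorptivities and residual diagnostics."""

    model: TitrationModel = field(repr=False)
    binding_model: BindingModel
    log_beta: np.ndarray
    log_beta_se: np.ndarray
    epsilon: dict
    rss: float
    residuals: np.ndarray
    aicc: float
    degenerate: bool

    @property
    def kc(self) -> float:
        """Stepwise association constant of the first complex, M^-1."""
        return float(10.0 ** self.log_beta[0])

    def trend(self, alpha: float = 0.05) -> TrendReport:
        """Residual-trend verdict over the titrated points.

        The guest-only reference rows (h_tot = 0) anchor the free-guest
        absorptivity rather than probe the binding curve, so they are
        excluded from the sign ordering before the runs tests.
        """
        mask = self.model.data.h_tot > 0
        return residual_trend_test(self.residuals[mask], alpha=alpha)

    def predicted(self) -> np.ndarray:
        return self.model.data.absorbance - self.residuals

    def to_dict(self) -> dict:
        tr = self.trend()
        return {
            "model": self.binding_model.name,
            "log_beta": list(map(float, self.log_beta)),
            "log_beta_se": [None if not np.isfinite(v) else float(v)
                            for v in self.log_beta_se],
            "kc_per_M": self.kc,
            "rss": self.rss,
            "aicc": self.aicc,
            "degenerate": self.degenerate,
            "systematic_trend": tr.systematic,
            "trend_fraction_rejecting": tr.fraction_rejecting,
        }

    def summary(self) -> str:
        tr = self.trend()
        lines = [
            f"Global titration fit: model {self.binding_model.name}",
            "-----------------------------------------------",
        ]
        for s, lb, se in zip(self.binding_model.species, self.log_beta, self.log_beta_se):
            se_txt = f"+/- {se:.3f}" if np.isfinite(se) else "(SE unavailable)"
            lines.append(f"log beta({s.name}) : {lb:.3f} {se_txt}")
        lines += [
            f"Kc (M^-1)      : {self.kc:.0f}",
            f"rss            : {self.rss:.3e}",
            f"AICc           : {self.aicc:.1f}",
            f"residual trend : {'systematic' if tr.systematic else 'no systematic trend'}"
            f" ({100 * tr.fraction_rejecting:.1f}% of wavelengths reject)",
        ]
        if self.degenerate:
            lines.append("WARNING: model unidentifiable on these data (flat rss)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs fitted absorbance across the titration; needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        pred = self.predicted()
        for i, h in enumerate(d.h_tot):
            ax.plot(d.wavelengths, d.absorbance[i], ".", ms=2)
            ax.plot(d.wavelengths, pred[i], "-", lw=0.8, label=f"h={h:.2e} M")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("absorbance")
        return ax


def fit_titration(data: TitrationData, model: BindingModel, starts: int = 7,
                  seed: int = 0) -> TitrationResults:
    """Functional wrapper around :class:`TitrationModel`."""
    return TitrationModel(data, model).fit(starts=starts, seed=seed)


@dataclass(frozen=True)
class ModelSelectionReport:
    """Candidate stoichiometries ranked by residual trend then AICc."""

    entries: tuple  # (name, TitrationResults | None, error str | None), ranked
    failures: tuple

    @property
    def best(self) -> TitrationResults:
        return self.entries[0][1]

    @property
    def best_name(self) -> str:
        return self.entries[0][0]

    def summary(self) -> str:
        lines = ["Stoichiometry model selection", "-----------------------------"]
        for rank, (name, res, _) in enumerate(self.entries, start=1):
            tr = res.trend()
            verdict = "systematic" if tr.systematic else "random"
            lines.append(
                f"{rank}. {name:10s} rss={res.rss:.3e} AICc={res.aicc:.1f} residuals={verdict}"
            )
        for name, err in self.failures:
            lines.append(f"   {name}: fit failed ({err})")
        return "\n".join(lines)


def select_model(data: TitrationData, candidates, alpha: float = 0.05,
                 seed: int = 0, starts: int = 7) -> ModelSelectionReport:
    """Fit every candidate binding model and rank them.

    Ranking: models whose residuals show no systematic trend come first;
    ties break on AICc, which charges the extra formation constant of the
    two-complex models.  Candidates whose fits fail are excluded and listed.
    """
    if len(candidates) < 1:
        raise ValidationError("at least one candidate model required")
    fitted, failures = [], []
    for cand in candidates:
        if isinstance(cand, str):
            cand = BindingModel.from_name(cand)
        try:
            res = TitrationModel(data, cand).fit(starts=starts, seed=seed)
        except (NumericalError, ValidationError) as exc:
            failures.append((cand.name, str(exc)))
            continue
        fitted.append((cand.name, res))
    if not fitted:
        raise NumericalError("every candidate model failed to fit")
    ranked = sorted(fitted, key=lambda t: (t[1].trend(alpha).systematic, t[1].aicc))
    return ModelSelectionReport(
        entries=tuple((n, r, None) for n, r in ranked),
        failures=tuple(failures),
    )
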