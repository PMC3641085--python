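"""Binomial mixed-effects response models.

The statistical unit is one caregiver vocalisation; the outcome is a binary
indicator of whether the infant produced a response (of a given subtype)
within the 3-second window.  The model is a logit GLMM

    logit P(y_ij = 1) = x_ij' beta + b_i,     b_i ~ N(0, sigma^2)

with a child-level random intercept b_i.  The marginal likelihood is
integrated by adaptive Gauss–Hermite quadrature (per-subject Laplace mode
plus Hermite nodes scaled by the mode curvature) and maximised with
L-BFGS-B over (beta, log sigma); standard errors come from the inverse of
the numerically differentiated Hessian at the optimum (Wald inference,
two-tailed p, alpha = 0.05).

Semester enters through successive-difference (backward) contrasts, so the
two reported coefficients are the S2-vs-S1 and S3-vs-S2 log-odds changes.
Group is coded AD vs TD (TD reference), speaker mother vs father (father
reference), speech type parentese vs other speech (other-speech reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from scipy.stats import norm

from .events import INFANT_METAS, InteractionLog, TOWARD_PEOPLE_METAS
from .interactions import ResponseBigram, _vocal_events
from .events import MetaBehaviorMap

RESPONSE_COLUMNS = ("any", "toward_people", *INFANT_METAS)

#: backward-difference contrast rows for the three semesters
_SEMESTER_CONTRASTS = {
    "S1": (-2.0 / 3.0, -1.0 / 3.0),
    "S2": (1.0 / 3.0, -1.0 / 3.0),
    "S3": (1.0 / 3.0, 2.0 / 3.0),
}

_FACTOR_CODINGS = {
    "group": ("group_AD_vs_TD", {"TD": 0.0, "AD": 1.0}),
    "speaker": ("speaker_mother_vs_father", {"father": 0.0, "mother": 1.0}),
    "speech_type": ("parentese_vs_other", {"other_speech": 0.0, "parentese": 1.0}),
}


def build_response_dataset(
    logs: Iterable[InteractionLog],
    bigrams: Iterable[ResponseBigram],
    include_other_speakers: bool = False,
    mapping: MetaBehaviorMap | None = None,
) -> pd.DataFrame:
    """One row per caregiver vocal event with binary response indicators.

    Indicators: one per infant meta-behavior subtype, plus ``toward_people``
    (OR of the five toward-people subtypes) and ``any`` (OR of everything).
    Speakers other than mother/father are dropped unless requested.
    """
    mapping = mapping or MetaBehaviorMap.default()
    responded: dict[int, set[str]] = {}
    for b in bigrams:
        if b.cg_meta == "vocal_solicitation":
            responded.setdefault(id(b.cg_event), set()).add(b.infant_meta)
    rows = []
    for log in logs:
        for e in _vocal_events(log, mapping):
            if e.speaker == "none" or e.speech_type == "none":
                raise ValueError(
                    f"vocal event at t={e.time_s} in {log.scene_id} lacks "
                    "speaker or speech_type"
                )
            if e.speaker == "other" and not include_other_speakers:
                continue
            metas = responded.get(id(e), set())
            row = {
                "child_id": log.child_id, "group": log.group,
                "semester": log.semester, "scene_id": log.scene_id,
                "speaker": e.speaker, "speech_type": e.speech_type,
            }
            for m in INFANT_METAS:
                row[m] = int(m in metas)
            row["toward_people"] = int(bool(metas & set(TOWARD_PEOPLE_METAS)))
            row["any"] = int(bool(metas))
            rows.append(row)
    return pd.DataFrame(rows)


def design_matrix(
    records: pd.DataFrame, fixed: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix with the package's factor codings.

    Requires every requested factor to show at least two observed levels
    (a single-semester dataset makes the successive contrasts inestimable).
    """
    cols: list[np.ndarray] = [np.ones(len(records))]
    names: list[str] = ["intercept"]
    for f in fixed:
        levels = set(records[f].unique())
        if len(levels) < 2:
            raise ValueError(
                f"factor {f!r} has a single observed level {levels}; "
                "contrast inestimable"
            )
        if f == "semester":
            if unknown := levels - set(_SEMESTER_CONTRASTS):
                raise ValueError(f"unknown semester levels {unknown}")
            c = records["semester"].map(_SEMESTER_CONTRASTS)
            cols.append(np.array([v[0] for v in c]))
            cols.append(np.array([v[1] for v in c]))
            names += ["sem2_vs_sem1", "sem3_vs_sem2"]
        elif f in _FACTOR_CODINGS:
            name, coding = _FACTOR_CODINGS[f]
            if unknown := levels - set(coding):
                raise ValueError(f"unknown levels {unknown} for factor {f!r}")
            cols.append(records[f].map(coding).to_numpy(dtype=float))
            names.append(name)
        else:
            cols.append(records[f].to_numpy(dtype=float))
            names.append(f)
    return np.column_stack(cols), names


@dataclass
class GlmmFit:
    """Fixed-effect table, random-intercept sd and fit diagnostics."""

    table: pd.DataFrame  # index: term; columns: estimate, se, z, p
    re_sd: float
    loglik: float
    converged: bool
    n_obs: int
    n_subjects: int
    response: str = ""
    notes: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def summary(self) -> str:
        head = (
            f"binomial GLMM ({self.response or 'response'}): "
            f"{self.n_obs} obs, {self.n_subjects} subjects, "
            f"random-intercept sd = {self.re_sd:.3f}, "
            f"loglik = {self.loglik:.2f}"
            + ("" if self.converged else "  [NOT CONVERGED]")
        )
        return head + "\n" + self.table.to_string(float_format=lambda v: f"{v:.4f}")


class _AGQLikelihood:
    """Marginal log-likelihood of the random-intercept logit model."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray, n_quad: int):
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order].astype(float)
        g = groups[order]
        _, starts = np.unique(g, return_index=True)
        self.slices = np.append(starts, len(g))
        self.n_groups = len(starts)
        # Hermite-e nodes integrate against the standard normal kernel
        z, w = hermegauss(n_quad)
        self.z = z
        self.logw = np.log(w / np.sqrt(2 * np.pi))

    def _group_mode(self, eta: np.ndarray, y: np.ndarray, sigma2: float) -> tuple[float, float]:
        """Newton mode and curvature of the joint log-density in b."""
        b = 0.0
        for _ in range(50):
            mu = expit(eta + b)
            grad = float(np.sum(y - mu)) - b / sigma2
            hess = -float(np.sum(mu * (1 - mu))) - 1.0 / sigma2
            step = grad / hess
            b -= step
            if abs(step) < 1e-9:
                break
        mu = expit(eta + b)
        hess = -float(np.sum(mu * (1 - mu))) - 1.0 / sigma2
        return b, hess

    def __call__(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = float(np.exp(log_sigma))
        sigma2 = sigma * sigma
        eta_all = self.X @ beta
        total = 0.0
        for gi in range(self.n_groups):
            s, e = self.slices[gi], self.slices[gi + 1]
            eta, y = eta_all[s:e], self.y[s:e]
            bhat, hess = self._group_mode(eta, y, sigma2)
            tau = 1.0 / np.sqrt(-hess)
            b_nodes = bhat + tau * self.z  # (Q,)
            eta_nodes = eta[:, None] + b_nodes[None, :]
            # Bernoulli log-lik at each node
            ll_nodes = np.sum(
                y[:, None] * log_expit(eta_nodes)
                + (1 - y[:, None]) * log_expit(-eta_nodes),
                axis=0,
            )
            log_prior = -0.5 * (b_nodes**2) / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
            # adaptive GH: integrand / N(bhat, tau^2) kernel, Hermite-e weights
            log_integrand = (
                ll_nodes + log_prior + 0.5 * self.z**2 + np.log(tau) + self.logw
            )
            m = log_integrand.max()
            total += m + np.log(np.sum(np.exp(log_integrand - m)))
        return total


def fit_glmm(
    records: pd.DataFrame,
    response: str = "any",
    fixed: Sequence[str] = ("semester", "group", "speaker", "speech_type"),
    group_col: str = "child_id",
    n_quad: int = 15,
    max_abs_beta: float = 15.0,
) -> GlmmFit:
    """Fit the binomial random-intercept GLMM.

    ``response`` names a 0/1 column of ``records``.  Raises on a constant
    response or fewer than two subjects; non-convergence and suspected
    complete separation are flagged on the returned fit, not raised.
    """
    if response not in records.columns:
        raise KeyError(f"no response column {response!r}")
    y = records[response].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"response {response!r} is constant")
    subjects = records[group_col].to_numpy()
    if len(np.unique(subjects)) < 2:
        raise ValueError("need at least two subjects for a random intercept")
    X, names = design_matrix(records, fixed)

    lik = _AGQLikelihood(X, y, subjects, n_quad)
    nll = lambda p: -lik(p)
    p0 = np.zeros(X.shape[1] + 1)
    p0[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
    p0[-1] = np.log(0.3)
    bounds = [(-max_abs_beta, max_abs_beta)] * X.shape[1] + [(-8.0, 3.0)]
    res = minimize(nll, p0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-11})

    notes: list[str] = []
    converged = bool(res.success)
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    if np.any(np.abs(beta) >= max_abs_beta - 1e-6):
        converged = False
        notes.append("coefficient at bound: possible complete separation")

    # observed-information SEs via central-difference Hessian on (beta, log sigma)
    k = len(res.x)
    h = 1e-4 * np.maximum(1.0, np.abs(res.x))
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = res.x.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = res.x.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = res.x.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = res.x.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            H[i, j] = H[j, i] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
        if np.any(se == 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se = np.full(k - 1, np.nan)
        converged = False
        notes.append("singular Hessian: standard errors unavailable")

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2 * norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": p}, index=pd.Index(names, name="term")
    )
    return GlmmFit(
        table=table, re_sd=sigma, loglik=float(-res.fun), converged=converged,
        n_obs=len(y), n_subjects=len(np.unique(subjects)),
        response=response, notes=notes,
    )


def fit_glmm_all_responses(
    records: pd.DataFrame,
    responses: Sequence[str] = RESPONSE_COLUMNS,
    **kwargs,
) -> pd.DataFrame:
    """Reporting table: rows = contrasts, columns = response subtypes.

    Cells hold "beta (se), p"; inestimable responses are left blank.
    """
    fits = {}
    for r in responses:
        try:
            fits[r] = fit_glmm(records, response=r, **kwargs)
        except ValueError:
            fits[r] = None
    estimable = [f for f in fits.values() if f is not None]
    if not estimable:
        raise ValueError("no response column was estimable on these records")
    terms = estimable[0].table.index
    out = pd.DataFrame(index=terms, columns=list(responses), dtype=object)
    for r, f in fits.items():
        if f is None:
            continue
        for t in f.table.index:
            row = f.table.loc[t]
            out.loc[t, r] = f"{row.estimate:+.3f} ({row.se:.3f}), p={row.p:.3g}"
    return out


def posthoc_suite(
    records: pd.DataFrame,
    response: str = "any",
    **kwargs,
) -> dict[str, dict]:
    """The two stratified post-hoc analyses.

    (a) per group: semester + speaker + speech type;
    (b) per group x semester: speaker + speech type.
    Strata that cannot support a fit carry a skip entry with the reason.
    """
    results: dict[str, dict] = {"by_group": {}, "by_group_semester": {}}
    for g, sub in records.groupby("group", observed=True):
        try:
            results["by_group"][g] = fit_glmm(
                sub, response=response,
                fixed=("semester", "speaker", "speech_type"), **kwargs,
            )
        except (ValueError, KeyError) as exc:
            results["by_group"][g] = {"skipped": str(exc)}
    for (g, s), sub in records.groupby(["group", "semester"], observed=True):
        try:
            results["by_group_semester"][(g, s)] = fit_glmm(
                sub, response=response, fixed=("speaker", "speech_type"), **kwargs,
            )
        except (ValueError, KeyError) as exc:
            results["by_group_semester"][(g, s)] = {"skipped": str(exc)}
    return results


def parentese_trend(
    vocal_records: pd.DataFrame,
    fixed: Sequence[str] = ("semester", "group"),
    **kwargs,
) -> GlmmFit:
    """Trend of parentese use over semesters (child random intercept).

    ``vocal_records`` has one row per vocalisation with a 0/1 ``parentese``
    column (plus semester/group/speaker/child_id).  With a single observed
    semester the successive contrasts are inestimable and this raises.
    """
    if "parentese" not in vocal_records.columns:
        raise KeyError("vocal_records needs a binary 'parentese' column")
    return fit_glmm(vocal_records, response="parentese", fixed=fixed, **kwargs)


def vocal_event_table(
    logs: Iterable[InteractionLog],
    include_other_speakers: bool = False,
    mapping: MetaBehaviorMap | None = None,
) -> pd.DataFrame:
    """Per-vocalisation table with the parentese indicator, for trend models."""
    mapping = mapping or MetaBehaviorMap.default()
    rows = []
    for log in logs:
        for e in _vocal_events(log, mapping):
            if e.speech_type == "none":
                raise ValueError("vocal event missing speech_type tag")
            if e.speaker == "other" and not include_other_speakers:
                continue
            rows.append(
                {
                    "child_id": log.child_id, "group": log.group,
                    "semester": log.semester, "speaker": e.speaker,
                    "parentese": int(e.speech_type == "parentese"),
                }
            )
    return pd.DataFrame(rows)


def simulate_records(
    n_obs: int,
    n_children: int,
    effects: dict[str, float] | None = None,
    re_sd: float = 0.5,
    seed: int = 0,
    intercept: float = -0.5,
) -> pd.DataFrame:
    """Simulate a response dataset directly from the GLMM.

    ``effects`` maps design-matrix term names (``sem2_vs_sem1``,
    ``sem3_vs_sem2``, ``group_AD_vs_TD``, ``speaker_mother_vs_father``,
    ``parentese_vs_other``) to true log-odds coefficients; unnamed terms are
    zero.  Children are split evenly between groups; semester, speaker and
    speech type are balanced at random within child.  This is the parameter-
    recovery surface for :func:`fit_glmm`.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    children = [f"c{i:03d}" for i in range(n_children)]
    child_group = {c: ("AD" if i < n_children // 2 else "TD") for i, c in enumerate(children)}
    b = dict(zip(children, rng.normal(0.0, re_sd, size=n_children)))
    df = pd.DataFrame(
        {
            "child_id": rng.choice(children, size=n_obs),
            "semester": rng.choice(["S1", "S2", "S3"], size=n_obs),
            "speaker": rng.choice(["mother", "father"], size=n_obs),
            "speech_type": rng.choice(["parentese", "other_speech"], size=n_obs),
        }
    )
    df["group"] = df["child_id"].map(child_group)
    X, names = design_matrix(df, ("semester", "group", "speaker", "speech_type"))
    beta = np.array([intercept] + [effects.get(n, 0.0) for n in names[1:]])
    eta = X @ beta + df["child_id"].map(b).to_numpy()
    df["response"] = (rng.random(n_obs) < expit(eta)).astype(int)
    return df
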