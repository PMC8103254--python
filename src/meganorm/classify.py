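"""Stepwise linear discriminant classification of subjects from regional
z-scores.

Variables (regions) enter a two-group discriminant model one at a time, each
step admitting the candidate that minimises Wilks' lambda (the ratio of
within-group to total scatter over the entered set), provided its partial F
exceeds ``f_to_enter``; entered variables whose partial F drops below
``f_to_remove`` are removed, and candidates nearly collinear with the entered
set (tolerance = 1 - R^2 below threshold) are skipped.  The selected set is
turned into Fisher classification functions (one linear function per group;
a subject is assigned to the group with the larger function value).

Accuracy is assessed by leave-one-out jackknife: the variable set stays
fixed, the classification-function coefficients are re-estimated with each
subject held out, and the held-out subject is classified.  Significance of a
confusion row is the exact fair-coin tail probability: classifying k of n
correctly is compared with getting more than k heads in n fair flips (the
strict-exceedance convention; an "at least" variant is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp


class ClassifierError(ValueError):
    pass


@dataclass
class StepwiseConfig:
    """Stepwise selection thresholds (SPSS-style conventions).

    ``f_to_enter``/``f_to_remove`` are partial-F thresholds; ``tolerance`` is
    the minimum 1 - R^2 of a candidate against the entered set (computed on
    the pooled within-group correlation matrix).
    """

    f_to_enter: float = 3.84
    f_to_remove: float = 2.71
    tolerance: float = 0.001
    max_steps: Optional[int] = None  # default 2 x n_regions
    priors: str = "equal"  # "equal" or "proportional"

    def validate(self) -> None:
        if not self.f_to_enter > self.f_to_remove > 0:
            raise ClassifierError("need f_to_enter > f_to_remove > 0")
        if not 0.0 < self.tolerance < 1.0:
            raise ClassifierError("tolerance must be in (0, 1)")
        if self.priors not in ("equal", "proportional"):
            raise ClassifierError(f"unknown priors {self.priors!r}")


@dataclass
class ClassifierModel:
    """Fisher two-group classification functions on the selected regions.

    ``coefficients[g]`` maps each selected region to its coefficient in group
    g's classification function; ``constants[g]`` is the additive term.
    ``signs`` marks each region "+"/"-" for elevated/depressed activity in
    the second (positive) group, doubled ("++"/"--") for the first-entered
    region, which makes the largest statistical contribution.
    """

    selected_regions: list[str]  # in entry order
    group_labels: tuple[str, str]
    coefficients: dict[str, dict[str, float]]  # group -> region -> coef
    constants: dict[str, float]
    signs: dict[str, str]
    wilks_lambda: list[float] = field(default_factory=list)  # after each entry

    @property
    def is_empty(self) -> bool:
        return not self.selected_regions

    def scores(self, X: np.ndarray, region_ids: Sequence[str]) -> np.ndarray:
        """Classification-function difference (positive-group minus
        negative-group function) for each row of X."""
        g0, g1 = self.group_labels
        if self.is_empty:
            return np.zeros(X.shape[0])
        idx = [list(region_ids).index(r) for r in self.selected_regions]
        c0 = np.array([self.coefficients[g0][r] for r in self.selected_regions])
        c1 = np.array([self.coefficients[g1][r] for r in self.selected_regions])
        return (X[:, idx] @ (c1 - c0)
                + (self.constants[g1] - self.constants[g0]))

    def classify(self, X: np.ndarray, region_ids: Sequence[str]) -> np.ndarray:
        """Assign each row to a group label.

        An empty model falls back to the priors; under equal priors the tie
        is broken deterministically in favour of the first group label.
        """
        s = self.scores(X, region_ids)
        g0, g1 = self.group_labels
        return np.where(s > 0, g1, g0)


@dataclass
class ClassificationReport:
    """Confusion counts with per-group accuracy and exact binomial p.

    ``confusion[i][j]``: subjects of group i classified as group j, with
    groups ordered as ``group_labels``.  Percentages are rounded
    half-away-from-zero to one decimal, matching tabular convention.
    """

    group_labels: tuple[str, str]
    confusion: np.ndarray  # 2x2 int
    pct_correct: dict[str, float]
    p_value: dict[str, float]
    jackknifed: bool

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used in printed tables);
    numpy's bankers rounding would turn 77.85 into 77.8."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def binomial_exceedance_p(correct: int, n: int,
                          convention: str = "strict") -> float:
    """Exact fair-coin tail probability for a classification row.

    ``strict`` (default): P(X > correct | n, 1/2) — the convention that
    reproduces published table p-values; note it yields exactly 0 for a
    perfect row.  ``at_least``: P(X >= correct | n, 1/2).  Computed by
    log-space summation of binomial terms, so extreme tails do not underflow
    prematurely.
    """
    if not 0 <= correct <= n:
        raise ClassifierError(f"need 0 <= correct <= n, got {correct}/{n}")
    if convention == "strict":
        lo = correct + 1
    elif convention == "at_least":
        lo = correct
    else:
        raise ClassifierError(f"unknown convention {convention!r}")
    if lo > n:
        return 0.0
    log_terms = [math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
                 - n * math.log(2.0) for k in range(lo, n + 1)]
    return float(math.exp(logsumexp(log_terms)))


# ---------------------------------------------------------------------------
# internal scatter-matrix helpers

def _scatter(X: np.ndarray, y01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total and within-group SSCP matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in (0, 1):
        Xg = X[y01 == g]
        Xgc = Xg - Xg.mean(axis=0)
        W += Xgc.T @ Xgc
    return T, W


def _wilks(T: np.ndarray, W: np.ndarray, cols: list[int]) -> float:
    if not cols:
        return 1.0
    Ts = T[np.ix_(cols, cols)]
    Ws = W[np.ix_(cols, cols)]
    sign_w, logdet_w = np.linalg.slogdet(Ws)
    sign_t, logdet_t = np.linalg.slogdet(Ts)
    if sign_w <= 0 or sign_t <= 0:
        raise ClassifierError("singular scatter matrix in Wilks' lambda")
    return float(np.exp(logdet_w - logdet_t))


def _tolerances(Rw: np.ndarray, entered: list[int],
                candidates: np.ndarray) -> np.ndarray:
    """1 - R^2 of each candidate against the entered set, on the pooled
    within-group correlation matrix."""
    if not entered:
        return np.ones(len(candidates))
    Rss = Rw[np.ix_(entered, entered)]
    out = np.empty(len(candidates))
    for i, v in enumerate(candidates):
        rvs = Rw[np.ix_([v], entered)][0]
        try:
            out[i] = 1.0 - float(rvs @ np.linalg.solve(Rss, rvs))
        except np.linalg.LinAlgError:
            out[i] = 0.0
    return out


def stepwise_lda(z_matrix: np.ndarray, labels: Sequence[str],
                 cfg: Optional[StepwiseConfig] = None,
                 region_ids: Optional[Sequence[str]] = None,
                 excluded_regions: Optional[set[str]] = None,
                 ) -> ClassifierModel:
    """Stepwise two-group discriminant selection with Fisher functions.

    ``labels`` must take exactly two values; the group ordering is
    (first-seen, second-seen), the second acting as the "positive" group for
    sign annotation.  ``excluded_regions`` are never considered (used by the
    second-step rerun).
    """
    cfg = cfg or StepwiseConfig()
    cfg.validate()
    X = np.asarray(z_matrix, dtype=float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ClassifierError(f"need exactly 2 groups, got {uniq}")
    g0, g1 = uniq
    y01 = (labels == g1).astype(int)
    n0, n1 = int((y01 == 0).sum()), int((y01 == 1).sum())
    if min(n0, n1) < 2:
        raise ClassifierError("need >= 2 subjects per group")
    n, p = X.shape
    if region_ids is None:
        region_ids = [f"var{i}" for i in range(p)]
    region_ids = list(region_ids)
    excluded_idx = {region_ids.index(r) for r in (excluded_regions or set())}

    T, W = _scatter(X, y01)
    dW = np.sqrt(np.diag(W))
    candidates_all = [j for j in range(p)
                      if j not in excluded_idx and dW[j] > 0]
    # constant columns among candidates violate the precondition; drop them
    with np.errstate(invalid="ignore", divide="ignore"):
        Rw = W / np.outer(dW, dW)
    Rw[~np.isfinite(Rw)] = 0.0

    entered: list[int] = []
    lam_path: list[float] = []
    lam = 1.0
    max_steps = cfg.max_steps if cfg.max_steps is not None else 2 * p
    g = 2  # groups

    for _ in range(max_steps):
        changed = False
        # removal pass
        if len(entered) > 1:
            p_in = len(entered)
            worst, worst_f = None, np.inf
            for v in entered:
                rest = [u for u in entered if u != v]
                lam_rest = _wilks(T, W, rest)
                f_rem = (lam_rest / lam - 1.0) * (n - g - p_in + 1) / (g - 1)
                if f_rem < worst_f:
                    worst, worst_f = v, f_rem
            if worst is not None and worst_f < cfg.f_to_remove:
                entered.remove(worst)
                lam = _wilks(T, W, entered)
                changed = True
                continue
        # entry pass
        pool = [j for j in candidates_all if j not in entered]
        if pool:
            tol = _tolerances(Rw, entered, np.array(pool))
            best, best_lam = None, np.inf
            p_in = len(entered)
            for j, t in zip(pool, tol):
                if t < cfg.tolerance:
                    continue
                try:
                    lam_new = _wilks(T, W, entered + [j])
                except ClassifierError:
                    continue
                if lam_new < best_lam:
                    best, best_lam = j, lam_new
            if best is not None and best_lam > 0:
                f_ent = (lam / best_lam - 1.0) * (n - g - p_in) / (g - 1)
                if f_ent >= cfg.f_to_enter:
                    entered.append(best)
                    lam = best_lam
                    lam_path.append(lam)
                    changed = True
        if not changed:
            break

    return _fisher_model(X, y01, (g0, g1), entered, region_ids, cfg,
                         lam_path)


def _fisher_model(X: np.ndarray, y01: np.ndarray,
                  group_labels: tuple[str, str], entered: list[int],
                  region_ids: list[str], cfg: StepwiseConfig,
                  lam_path: list[float]) -> ClassifierModel:
    g0, g1 = group_labels
    sel = [region_ids[j] for j in entered]
    if not entered:
        return ClassifierModel(sel, group_labels, {g0: {}, g1: {}},
                               {g0: 0.0, g1: 0.0}, {}, lam_path)
    coefs, consts = _fisher_functions(X[:, entered], y01, cfg.priors)
    mu0 = X[np.asarray(y01) == 0][:, entered].mean(axis=0)
    mu1 = X[np.asarray(y01) == 1][:, entered].mean(axis=0)
    signs = {}
    for k, r in enumerate(sel):
        ch = "+" if mu1[k] > mu0[k] else "-"
        signs[r] = ch * 2 if k == 0 else ch
    return ClassifierModel(
        sel, group_labels,
        {g0: dict(zip(sel, coefs[0].tolist())),
         g1: dict(zip(sel, coefs[1].tolist()))},
        {g0: float(consts[0]), g1: float(consts[1])},
        signs, lam_path)


def _fisher_functions(Xs: np.ndarray, y01: np.ndarray, priors: str,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Fisher classification-function coefficients and constants for the two
    groups, from the pooled within-group covariance."""
    n = Xs.shape[0]
    mus, ns = [], []
    W = np.zeros((Xs.shape[1], Xs.shape[1]))
    for g in (0, 1):
        Xg = Xs[y01 == g]
        mu = Xg.mean(axis=0)
        Xgc = Xg - mu
        W += Xgc.T @ Xgc
        mus.append(mu)
        ns.append(len(Xg))
    Sw = W / (n - 2)
    try:
        Sw_inv = np.linalg.inv(Sw)
    except np.linalg.LinAlgError as exc:
        raise ClassifierError("singular within-group covariance") from exc
    coefs = np.array([Sw_inv @ mu for mu in mus])
    pri = (np.array([0.5, 0.5]) if priors == "equal"
           else np.array(ns, dtype=float) / n)
    consts = np.array([-0.5 * mu @ Sw_inv @ mu + np.log(pg)
                       for mu, pg in zip(mus, pri)])
    return coefs, consts


def jackknife_classify(z_matrix: np.ndarray, labels: Sequence[str],
                       model_regions: Sequence[str],
                       cfg: Optional[StepwiseConfig] = None,
                       region_ids: Optional[Sequence[str]] = None,
                       binomial_convention: str = "strict",
                       ) -> ClassificationReport:
    """Leave-one-out classification with the variable set held fixed.

    For each subject the classification-function coefficients are
    re-estimated on the remaining subjects and the held-out subject is
    classified; the confusion counts, one-decimal percentages and exact
    binomial p-values are tabulated per group.
    """
    cfg = cfg or StepwiseConfig()
    cfg.validate()
    X = np.asarray(z_matrix, dtype=float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ClassifierError(f"need exactly 2 groups, got {uniq}")
    g0, g1 = uniq
    y01 = (labels == g1).astype(int)
    n = X.shape[0]
    if region_ids is None:
        region_ids = [f"var{i}" for i in range(X.shape[1])]
    region_ids = list(region_ids)
    idx = [region_ids.index(r) for r in model_regions]

    predicted = np.empty(n, dtype=int)
    if not idx:
        # empty model: prior fallback, deterministic tie-break to first group
        predicted[:] = 0
    else:
        Xs = X[:, idx]
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            Xtr, ytr = Xs[mask], y01[mask]
            if min((ytr == 0).sum(), (ytr == 1).sum()) < 2:
                raise ClassifierError("held-out fold leaves a group with < 2")
            try:
                coefs, consts = _fisher_functions(Xtr, ytr, cfg.priors)
            except ClassifierError:
                raise
            f = Xs[i] @ coefs.T + consts
            predicted[i] = int(f[1] > f[0])
            mask[i] = True

    confusion = np.zeros((2, 2), dtype=int)
    for truth, pred in zip(y01, predicted):
        confusion[truth, pred] += 1
    return _build_report((g0, g1), confusion, jackknifed=True,
                         convention=binomial_convention)


def resubstitution_classify(z_matrix: np.ndarray, labels: Sequence[str],
                            model: ClassifierModel,
                            region_ids: Sequence[str],
                            binomial_convention: str = "strict",
                            ) -> ClassificationReport:
    """Classify the training sample with the fitted model (no hold-out)."""
    labels = np.asarray(labels)
    g0, g1 = model.group_labels
    pred = model.classify(np.asarray(z_matrix, dtype=float), region_ids)
    confusion = np.zeros((2, 2), dtype=int)
    for truth, p in zip(labels, pred):
        confusion[int(truth == g1), int(p == g1)] += 1
    return _build_report((g0, g1), confusion, jackknifed=False,
                         convention=binomial_convention)


def _build_report(group_labels: tuple[str, str], confusion: np.ndarray,
                  jackknifed: bool, convention: str) -> ClassificationReport:
    pct, pval = {}, {}
    for gi, glab in enumerate(group_labels):
        row_n = int(confusion[gi].sum())
        correct = int(confusion[gi, gi])
        pct[glab] = round_half_away(100.0 * correct / row_n) if row_n else np.nan
        pval[glab] = (binomial_exceedance_p(correct, row_n, convention)
                      if row_n else np.nan)
    return ClassificationReport(group_labels, confusion, pct, pval, jackknifed)


def second_step_rerun(z_matrix: np.ndarray, labels: Sequence[str],
                      cfg: Optional[StepwiseConfig],
                      first_model: ClassifierModel,
                      region_ids: Sequence[str],
                      binomial_convention: str = "strict",
                      ) -> tuple[ClassifierModel, ClassificationReport]:
    """Re-run selection with the first model's regions excluded, then
    jackknife the second model.  Confirms whether information about the
    grouping persists in regions correlated with the first selection."""
    if first_model.is_empty:
        raise ClassifierError("first model selected no regions")
    model = stepwise_lda(z_matrix, labels, cfg, region_ids,
                         excluded_regions=set(first_model.selected_regions))
    report = jackknife_classify(z_matrix, labels, model.selected_regions, cfg,
                                region_ids, binomial_convention)
    return model, report


def discriminant_scores(z_matrix: np.ndarray, labels: Sequence[str],
                        model: ClassifierModel,
                        region_ids: Sequence[str]) -> np.ndarray:
    """Canonical discriminant score per subject.

    The canonical axis is Sw^{-1}(mu_pos - mu_neg) over the selected regions,
    centred on the grand mean and scaled to unit pooled within-group
    variance; positive scores lean toward the positive (second) group.
    """
    if model.is_empty:
        raise ClassifierError("empty model has no discriminant axis")
    X = np.asarray(z_matrix, dtype=float)
    labels = np.asarray(labels)
    g0, g1 = model.group_labels
    idx = [list(region_ids).index(r) for r in model.selected_regions]
    Xs = X[:, idx]
    y01 = (labels == g1).astype(int)
    n = Xs.shape[0]
    W = np.zeros((Xs.shape[1], Xs.shape[1]))
    mus = []
    for g in (0, 1):
        Xg = Xs[y01 == g]
        mu = Xg.mean(axis=0)
        W += (Xg - mu).T @ (Xg - mu)
        mus.append(mu)
    Sw = W / (n - 2)
    w = np.linalg.solve(Sw, mus[1] - mus[0])
    s = (Xs - Xs.mean(axis=0)) @ w
    within_var = float(w @ Sw @ w)
    return s / math.sqrt(within_var) if within_var > 0 else s


def score_group_test(scores: np.ndarray, labels: Sequence[str],
                     positive_label: Optional[str] = None,
                     ) -> tuple[float, float, float, float, float]:
    """Welch's t-test on per-subject discriminant scores, plus Levene's F.

    Returns ``(t, df_adjusted, p, levene_F, levene_p)``.  Levene's statistic
    (centred on the mean) tests equality of group variances; the t statistic
    uses the unequal-variance Welch form with Welch-Satterthwaite adjusted
    degrees of freedom (the conservative choice), and the one-sided p is
    taken in the direction of the positive group having larger scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ClassifierError(f"need exactly 2 groups, got {uniq}")
    if positive_label is None:
        positive_label = uniq[1]
    neg = scores[labels != positive_label]
    pos = scores[labels == positive_label]
    if min(len(neg), len(pos)) < 2:
        raise ClassifierError("need >= 2 subjects per group")
    v_neg, v_pos = neg.var(ddof=1), pos.var(ddof=1)
    if v_neg == 0 and v_pos == 0:
        raise ClassifierError("zero variance in both groups")
    se2_neg, se2_pos = v_neg / len(neg), v_pos / len(pos)
    t = (pos.mean() - neg.mean()) / math.sqrt(se2_neg + se2_pos)
    df = ((se2_neg + se2_pos) ** 2
          / (se2_neg ** 2 / (len(neg) - 1) + se2_pos ** 2 / (len(pos) - 1)))
    p = float(stats.t.sf(t, df))  # one-sided: positive group higher
    lev_F, lev_p = stats.levene(neg, pos, center="mean")
    return float(t), float(df), p, float(lev_F), float(lev_p)


def coincidence_and_correlation(symptom_status: "np.ndarray | Sequence",
                                scores: np.ndarray,
                                symptom_names: Sequence[str],
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise both-positive fractions and classifier-score correlations.

    ``symptom_status`` is subjects x symptoms boolean (screened positive);
    ``scores`` is subjects x classifiers (same symptom order).  Returns the
    symmetric matrices (coincidence fractions, Pearson correlations).
    """
    status = np.asarray(symptom_status, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    k = status.shape[1]
    if len(symptom_names) != k or scores.shape[1] != k:
        raise ClassifierError("symptom_names, status and scores disagree")
    if k < 2:
        raise ClassifierError("need >= 2 symptoms")
    n = status.shape[0]
    coincidence = (status.T.astype(float) @ status.astype(float)) / n
    corr = np.corrcoef(scores, rowvar=False)
    return coincidence, corr
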