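"""Integrated radio-clinical-genomic risk scores and outcome classifiers.

Three linear risk-score presets combine imaging, clinical and genomic
variables with published coefficients:

    iRCG = 4.44*cluDiss + 3.72*age + 2.11*CNB
    CCG  = 2.86*age + 1.85*sites + 1.17*CNB + 0.235*resection
    aRCG = 2.08*age + 1.30*CNB + 1.22*resection + 0.10*SZN + 1.26*coarseness
           + 1.73*Sobel.mean + 0.30*Gabor(45,2).kurtosis + 1.41*Gabor(90,2).mean
           + 0.30*Gabor(90,2).skewness + 1.91*Gabor(135,2).mean

Variables enter in raw units (age in years, CNB as a fraction, cluDiss as
computed); resection is encoded ordinally complete=0, optimal=1,
suboptimal=2, stage III=0, IV=1.  Patients at or above a cutoff are high
risk.  The platinum-resistance protocol is a linear-margin classifier under
repeated stratified 3-fold cross-validation with SMOTE applied to training
folds only; the averaged-radiomics variant adds nested recursive feature
elimination over {5, 10, 15, 20, 25} features.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ProtocolError, ValidationError
from .features import resolve_feature_alias

RESECTION_CODE = {"complete": 0.0, "optimal": 1.0, "suboptimal": 2.0}
STAGE_CODE = {"III": 0.0, "IV": 1.0}

DEFAULT_CUTPOINTS = {"iRCG": 642.00, "cluDiss": 68.62}


@dataclass
class ScoreCoefficients:
    name: str
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        bad = [k for k, v in self.coefficients.items() if not np.isfinite(v)]
        if bad:
            raise ValidationError(f"non-finite coefficients for {bad}")


IRCG_PFS = ScoreCoefficients("iRCG", {"cluDiss": 4.44, "age": 3.72, "CNB": 2.11})
CCG_PFS = ScoreCoefficients(
    "CCG", {"age": 2.86, "sites": 1.85, "CNB": 1.17, "resection": 0.235}
)
ARCG_PFS = ScoreCoefficients(
    "aRCG",
    {
        "age": 2.08,
        "CNB": 1.30,
        "resection": 1.22,
        "SZN": 0.10,
        "coarseness": 1.26,
        "Sobel.mean": 1.73,
        "Gabor(45,2).kurtosis": 0.30,
        "Gabor(90,2).mean": 1.41,
        "Gabor(90,2).skewness": 0.30,
        "Gabor(135,2)": 1.91,  # bare filter term: its mean statistic
    },
)

PRESETS = {"ircg": IRCG_PFS, "ccg": CCG_PFS, "arcg": ARCG_PFS}


@dataclass
class CutpointConfig:
    score_name: str
    cutoff: float
    method: str = "youden"
    direction: str = "ge"  # "ge": high risk iff score >= cutoff
    youden: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValidationError("cutoff must be finite")


@dataclass
class RiskScore:
    patient_id: str
    value: float
    model: str
    risk_group: str | None = None  # "low" | "high"


def resolve_variables(
    clinical=None, conventional=None, cludiss_result=None, features=None, extra=None
) -> dict[str, float]:
    """Flatten domain objects into the named numeric map scores draw from."""
    out: dict[str, float] = {}
    if clinical is not None:
        out["age"] = float(clinical.age)
        out["CNB"] = float(clinical.cnb)
        out["stage"] = STAGE_CODE[clinical.stage]
        out["resection"] = RESECTION_CODE[clinical.resection]
    if conventional is not None:
        out["TTV"] = float(conventional.ttv_cc)
        out["sites"] = float(conventional.n_sites)
    if cludiss_result is not None:
        out["cluDiss"] = float(cludiss_result.value)
    if features is not None:
        out.update({k: float(v) for k, v in features.values.items()})
    if extra:
        out.update({k: float(v) for k, v in extra.items()})
    return out


def evaluate_score(
    coeffs: ScoreCoefficients,
    variables: dict[str, float],
    cutpoint: CutpointConfig | None = None,
    patient_id: str = "",
) -> RiskScore:
    """Linear combination sum(coefficient * variable) in raw units."""
    total = 0.0
    for name, beta in coeffs.coefficients.items():
        if name in variables:
            v = variables[name]
        else:
            alias = resolve_feature_alias(name)
            if alias not in variables:
                raise ValidationError(f"score {coeffs.name!r}: unresolved variable {name!r}")
            v = variables[alias]
        if not np.isfinite(v):
            raise ValidationError(f"score {coeffs.name!r}: non-finite variable {name!r}")
        total += beta * float(v)
    group = None
    if cutpoint is not None:
        if cutpoint.direction == "ge":
            group = "high" if total >= cutpoint.cutoff else "low"
        else:
            group = "high" if total <= cutpoint.cutoff else "low"
    return RiskScore(patient_id=patient_id, value=total, model=coeffs.name, risk_group=group)


# ---------------------------------------------------------------------------
# elastic-net score fitting and ROC cut point
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetConfig:
    alpha: float = 1.0          # mixing (1 = lasso)
    lam: float = 0.1            # penalty strength
    tuning_grid: list[tuple[float, float]] | None = None
    cv_folds: int = 3
    seed: int = 0
    max_iter: int = 50_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("mixing alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValidationError("penalty lambda must be >= 0")


def fit_linear_risk_score(
    features: pd.DataFrame, outcome: pd.Series, config: ElasticNetConfig | None = None
) -> ScoreCoefficients:
    """Elastic-net linear fit of a continuous outcome (e.g. PFS months).

    Rows with missing values or outcomes are excluded.  Coefficients are on
    raw variable units; sparsity increases with the mixing parameter.
    """
    from sklearn.linear_model import ElasticNet
    from sklearn.model_selection import GridSearchCV, KFold

    config = config or ElasticNetConfig()
    df = features.copy()
    df["__y"] = np.asarray(outcome, dtype=float)
    df = df.dropna()
    if len(df) < 10:
        raise ProtocolError(f"need >= 10 complete patients, have {len(df)}")
    y = df.pop("__y").to_numpy()
    X = df.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("constant outcome: elastic net is degenerate")

    if config.tuning_grid:
        grid = {
            "l1_ratio": sorted({a for a, _ in config.tuning_grid}),
            "alpha": sorted({l for _, l in config.tuning_grid}),
        }
        cv = KFold(config.cv_folds, shuffle=True, random_state=config.seed)
        search = GridSearchCV(
            ElasticNet(max_iter=config.max_iter), grid, cv=cv,
            scoring="neg_mean_squared_error",
        )
        search.fit(X, y)
        model = search.best_estimator_
    else:
        # l1_ratio=0 with plain ElasticNet is ridge; keep a tiny l1 floor out
        model = ElasticNet(
            alpha=max(config.lam, 1e-12), l1_ratio=config.alpha, max_iter=config.max_iter
        )
        model.fit(X, y)
    return ScoreCoefficients(
        name="fitted", coefficients=dict(zip(df.columns, map(float, model.coef_)))
    )


def find_cutpoint(
    scores: np.ndarray, outcome: np.ndarray, score_name: str = "score"
) -> CutpointConfig:
    """Youden-optimal ROC cut point; ties broken toward the lower cutoff.

    If the score is anti-concordant with the outcome the direction flag flips
    to "le" with the same |Youden| statistic.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    if len(np.unique(outcome)) < 2:
        raise ProtocolError("both outcome classes must be present")

    def best(s):
        fpr, tpr, thr = roc_curve(outcome, s)
        youden = tpr - fpr
        ties = np.flatnonzero(youden == youden.max())
        finite = thr[ties][np.isfinite(thr[ties])]
        cut = float(finite.min()) if len(finite) else float(thr[ties].min())
        return float(youden.max()), cut

    y_ge, cut_ge = best(scores)
    y_le, cut_le = best(-scores)
    if y_ge >= y_le:
        return CutpointConfig(score_name, cut_ge, direction="ge", youden=y_ge)
    return CutpointConfig(score_name, -cut_le, direction="le", youden=y_le)


# ---------------------------------------------------------------------------
# SMOTE + repeated cross-validated linear-margin classification
# ---------------------------------------------------------------------------

def smote_oversample(
    X: np.ndarray, y: np.ndarray, seed: int, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolated minority samples (minority kNN, k<=5).

    The random stream is derived from ``seed`` and the training content only,
    so held-out data can never influence the synthetic samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ProtocolError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X, y
    Xm = X[y == minority]
    content = zlib.crc32(np.ascontiguousarray(Xm).tobytes())
    rng = np.random.default_rng(np.random.SeedSequence([seed, content]))
    if len(Xm) == 1:
        synth = np.repeat(Xm, n_needed, axis=0)
    else:
        kk = min(k, len(Xm) - 1)
        d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :kk]
        base = rng.integers(len(Xm), size=n_needed)
        pick = nn[base, rng.integers(kk, size=n_needed)]
        gap = rng.random((n_needed, 1))
        synth = Xm[base] + gap * (Xm[pick] - Xm[base])
    return np.vstack([X, synth]), np.concatenate([y, np.full(n_needed, minority)])


@dataclass
class ClassifierProtocol:
    folds: int = 3
    repeats: int = 100
    C: float = 1.0
    use_rfe: bool = False
    rfe_grid: tuple[int, ...] = (5, 10, 15, 20, 25)
    inner_folds: int = 3
    smote_k: int = 5
    seed: int = 0


@dataclass
class ClassifierReport:
    auroc: float
    auroc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    per_rep_auroc: np.ndarray
    importances: dict[str, float]
    fold_details: list[dict] = field(default_factory=list)
    n_features_selected: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auroc <= 1.0:
            raise ValidationError("AUROC outside [0, 1]")


def _pct_ci(values: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))


def _rfe_select(Xtr, ytr, protocol, rng) -> np.ndarray:
    """Nested CV over the RFE feature-count grid; returns selected column mask."""
    from sklearn.feature_selection import RFE
    from sklearn.model_selection import StratifiedKFold
    from sklearn.metrics import roc_auc_score
    from sklearn.svm import LinearSVC

    grid = [n for n in protocol.rfe_grid if n <= Xtr.shape[1]] or [Xtr.shape[1]]
    best_n, best_score = grid[0], -np.inf
    inner = StratifiedKFold(
        protocol.inner_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    for n in grid:
        aucs = []
        for tr, te in inner.split(Xtr, ytr):
            if len(np.unique(ytr[tr])) < 2 or len(np.unique(ytr[te])) < 2:
                continue
            sel = RFE(LinearSVC(C=protocol.C), n_features_to_select=n, step=0.2)
            sel.fit(Xtr[tr], ytr[tr])
            svc = LinearSVC(C=protocol.C).fit(Xtr[tr][:, sel.support_], ytr[tr])
            aucs.append(
                roc_auc_score(ytr[te], svc.decision_function(Xtr[te][:, sel.support_]))
            )
        score = np.mean(aucs) if aucs else -np.inf
        if score > best_score:
            best_score, best_n = score, n
    sel = RFE(LinearSVC(C=protocol.C), n_features_to_select=best_n, step=0.2)
    sel.fit(Xtr, ytr)
    return sel.support_


def train_platinum_classifier(
    features: pd.DataFrame, labels: pd.Series | np.ndarray,
    protocol: ClassifierProtocol | None = None,
) -> ClassifierReport:
    """Repeated stratified 3-fold CV of a linear SVM with per-fold SMOTE.

    Out-of-fold decision scores are pooled per repetition into AUROC,
    sensitivity and specificity (positive class = label 1, the resistant /
    minority class); 95% CIs are percentiles over repetitions and variable
    importances are mean |standardized weights| rescaled so the maximum is
    100.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    protocol = protocol or ClassifierProtocol()
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ProtocolError(f"need two classes with >= 2 members, have {dict(zip(classes, counts))}")
    if counts.min() < protocol.folds:
        raise ProtocolError("minority class smaller than the fold count")

    rng = np.random.default_rng(protocol.seed)
    rep_auroc, rep_sens, rep_spec = [], [], []
    weight_sum = np.zeros(X.shape[1])
    weight_n = 0
    fold_details: list[dict] = []
    n_selected: list[int] = []

    for rep in range(protocol.repeats):
        skf = StratifiedKFold(
            protocol.folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        oof_score = np.empty(len(y))
        oof_pred = np.empty(len(y), dtype=int)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            scaler = StandardScaler().fit(X[tr])
            Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
            ytr = y[tr]
            support = np.ones(X.shape[1], dtype=bool)
            if protocol.use_rfe:
                support = _rfe_select(Xtr, ytr, protocol, rng)
                n_selected.append(int(support.sum()))
            Xb, yb = smote_oversample(
                Xtr[:, support], ytr, seed=protocol.seed, k=protocol.smote_k
            )
            svc = SVC(kernel="linear", C=protocol.C).fit(Xb, yb)
            oof_score[te] = svc.decision_function(Xte[:, support])
            oof_pred[te] = (oof_score[te] >= 0).astype(int)
            w = np.zeros(X.shape[1])
            w[support] = np.abs(svc.coef_.ravel())
            weight_sum += w
            weight_n += 1
            if rep < 5:  # keep a bounded audit trail of the fold protocol
                cb, cc = np.unique(yb, return_counts=True)
                fold_details.append(
                    {
                        "repetition": rep,
                        "fold": fold,
                        "train_index": tr.copy(),
                        "test_index": te.copy(),
                        "balanced_counts": dict(zip(cb.tolist(), cc.tolist())),
                    }
                )
        rep_auroc.append(roc_auc_score(y, oof_score))
        tp = int(((oof_pred == 1) & (y == 1)).sum())
        fn = int(((oof_pred == 0) & (y == 1)).sum())
        tn = int(((oof_pred == 0) & (y == 0)).sum())
        fp = int(((oof_pred == 1) & (y == 0)).sum())
        rep_sens.append(tp / (tp + fn) if tp + fn else 0.0)
        rep_spec.append(tn / (tn + fp) if tn + fp else 0.0)

    rep_auroc = np.asarray(rep_auroc)
    mean_w = weight_sum / weight_n
    top = mean_w.max() if mean_w.max() > 0 else 1.0
    importances = {n: float(100.0 * w / top) for n, w in zip(names, mean_w)}
    return ClassifierReport(
        auroc=float(rep_auroc.mean()),
        auroc_ci=_pct_ci(rep_auroc),
        sensitivity=float(np.mean(rep_sens)),
        sensitivity_ci=_pct_ci(np.asarray(rep_sens)),
        specificity=float(np.mean(rep_spec)),
        specificity_ci=_pct_ci(np.asarray(rep_spec)),
        per_rep_auroc=rep_auroc,
        importances=importances,
        fold_details=fold_details,
        n_features_selected=n_selected,
    )


def compare_classifiers(a: ClassifierReport, b: ClassifierReport) -> float:
    """Two-sided paired test on per-repetition AUROC differences."""
    if len(a.per_rep_auroc) != len(b.per_rep_auroc):
        raise ProtocolError("reports have different repetition counts")
    diff = a.per_rep_auroc - b.per_rep_auroc
    if np.allclose(diff, 0):
        return 1.0
    return float(sps.wilcoxon(a.per_rep_auroc, b.per_rep_auroc).pvalue)


# ---------------------------------------------------------------------------
# robustness and correlation screens
# ---------------------------------------------------------------------------

def scanner_robustness_screen(
    features: pd.DataFrame, scanner: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Two-sided rank-sum per feature, GE vs non-GE; robust iff p > 0.05."""
    labels = np.asarray([str(s) for s in scanner])
    is_ge = labels == "GE"
    if is_ge.all() or not is_ge.any():
        raise ProtocolError("both GE and non-GE groups must be non-empty")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        constant = np.ptp(x) == 0
        if constant:
            p = 1.0
        else:
            p = float(sps.mannwhitneyu(x[is_ge], x[~is_ge], alternative="two-sided").pvalue)
        rows.append({"feature": col, "p_value": p, "robust": p > 0.05, "constant": constant})
    return pd.DataFrame(rows).set_index("feature")


def correlation_screen(
    radiomic: pd.DataFrame, enrichment: pd.DataFrame, min_pairs: int = 5
) -> dict[str, pd.DataFrame]:
    """Spearman rho/p per (feature, score) pair with p<0.05 flags and BH q-values."""
    common = radiomic.index.intersection(enrichment.index)
    r = radiomic.loc[common]
    e = enrichment.loc[common]
    rho = pd.DataFrame(index=r.columns, columns=e.columns, dtype=float)
    pval = rho.copy()
    evaluable = pd.DataFrame(False, index=r.columns, columns=e.columns)
    for fc in r.columns:
        for ec in e.columns:
            pair = pd.concat([r[fc], e[ec]], axis=1).dropna()
            if len(pair) < min_pairs:
                continue
            res = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho.loc[fc, ec] = float(res.statistic)
            pval.loc[fc, ec] = float(res.pvalue)
            evaluable.loc[fc, ec] = True
    flat = pval.to_numpy(dtype=float).ravel()
    q = np.full_like(flat, np.nan)
    ok = np.isfinite(flat)
    if ok.any():
        q[ok] = sps.false_discovery_control(flat[ok])
    qdf = pd.DataFrame(q.reshape(pval.shape), index=pval.index, columns=pval.columns)
    return {
        "rho": rho,
        "p": pval,
        "significant": (pval < 0.05) & evaluable,
        "q": qdf,
        "evaluable": evaluable,
    }


# ---------------------------------------------------------------------------
# thin survival-association contracts (delegated to lifelines)
# ---------------------------------------------------------------------------

def survival_association(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> dict[str, float]:
    """Cox PH association of a score with PFS: per-unit HR, Wald CI, concordance."""
    from lifelines import CoxPHFitter

    scores = np.asarray(scores, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < 1:
        raise ValidationError("no events observed")
    if np.ptp(scores) == 0:
        raise ValidationError("constant score: Cox fit is degenerate")
    df = pd.DataFrame({"score": scores, "time": np.asarray(time, dtype=float), "event": event})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["score"]
    return {
        "hr": float(s["exp(coef)"]),
        "hr_ci": (float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
        "log_hr": float(s["coef"]),
        "p": float(s["p"]),
        "concordance": float(cph.concordance_index_),
    }


def kaplan_meier_by_group(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> dict:
    """Per-group KM median survival plus the log-rank p between groups."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    summaries = {}
    for g in np.unique(group):
        kmf = KaplanMeierFitter()
        kmf.fit(time[group == g], event[group == g], label=str(g))
        summaries[str(g)] = {
            "n": int((group == g).sum()),
            "events": int(event[group == g].sum()),
            "median_survival": float(kmf.median_survival_time_),
        }
    p = float(multivariate_logrank_test(time, group, event).p_value)
    return {"groups": summaries, "logrank_p": p}


def pca_group_contrast(
    table: pd.DataFrame, groups: pd.Series | np.ndarray, n_components: int = 2
) -> dict[str, pd.DataFrame]:
    """Per-group PCA loading tables (columns scaled before decomposition)."""
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        sub = table.loc[groups == g]
        Z = StandardScaler().fit_transform(sub.to_numpy(dtype=float))
        k = min(n_components, Z.shape[0] - 1, Z.shape[1])
        pca = PCA(n_components=k).fit(Z)
        load = pd.DataFrame(
            pca.components_.T,
            index=table.columns,
            columns=[f"PC{i+1}" for i in range(k)],
        )
        load.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
        out[str(g)] = load
    return out
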