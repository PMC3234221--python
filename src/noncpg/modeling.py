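"""Predictive models linking methylation to expression, sequence and chromatin.

Three model families:

* a sample-level OLS model predicting mean CpA methylation from the log
  expression of DNMT3A/B, DNMT1 and the pluripotency factors OCT4, SOX2 and
  NANOG, followed by sequential ANOVA to rank predictors;
* tile-level OLS models over 1 kb windows predicting mean CpA (or CpG/CpT)
  methylation from sequence composition, repeat content, the other
  contexts' methylation, H3K36me3 presence and the cross-sample
  conservation score — with CpG-density variables deliberately excluded
  when predicting CpA methylation;
* a site-level classification protocol: 30 features per CpA computed on
  +/-10 bp windows, a 5% level threshold defining the methylated class,
  random down-sampling of the unmethylated majority to a balanced set, and
  stratified 10-fold cross-validated AUC for logistic regression, linear
  SVM and random forests (500 trees), with feature importances taken from a
  full-data fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from ._seq import revcomp
from .calling import SampleTable, load_genome
from .filtering import coverage_matrix, level_matrix
from .variation import conservation_scores, COVERAGE_CAP

EXPRESSION_PREDICTORS = ["DNMT3A", "DNMT3B", "DNMT1", "OCT4", "SOX2", "NANOG"]

#: Fixed predictor order for sequential (type-I) ANOVA in the tile models.
#: T content is omitted: the four base fractions sum to 1, so including all
#: of them with an intercept would make the design rank deficient.
TILE_PREDICTORS = [
    "a_content", "c_content", "g_content", "repeat_content",
    "cpa_content", "cpa_cpg_ratio", "cpc_level", "cpg_level",
    "cpt_level", "h3k36me3", "conservation",
]
CPG_DENSITY_PREDICTORS = ["cpg_content", "cpa_cpg_ratio"]


@dataclass
class LinearModelResult:
    response: str
    params: pd.Series
    r_squared: float
    f_pvalue: float
    anova: pd.DataFrame          # sequential (type-I) table
    ranking: list[str]           # predictors by descending F
    fit: object = field(repr=False, default=None)


def _ols_with_anova(df: pd.DataFrame, response: str,
                    predictors: list[str]) -> LinearModelResult:
    present = [p for p in predictors if p in df.columns]
    dropped = [p for p in predictors if p not in df.columns]
    if dropped:
        import warnings
        warnings.warn(f"predictors missing from table, dropped: {dropped}",
                      stacklevel=3)
    formula = f"{response} ~ " + " + ".join(present)
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    ranked = (
        anova.drop(index="Residual")
        .sort_values("F", ascending=False)
        .index.tolist()
    )
    return LinearModelResult(
        response=response,
        params=fit.params,
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        anova=anova,
        ranking=ranked,
        fit=fit,
    )


def sample_level_model(
    rows: pd.DataFrame,
    response: str = "mean_cpa",
    predictors: list[str] | None = None,
) -> LinearModelResult:
    """OLS of per-sample mean CpA level on marker-gene expression.

    ``rows`` has one row per sample with the response column and log
    expression columns (normalised to the ES-cell mean). Sequential ANOVA
    ranks predictors by F; with the default order DNMT3A and DNMT3B enter
    first, matching their biological priority as de novo methyltransferases.
    """
    if len(rows) < 10:
        raise ValueError("need >= 10 samples for the sample-level model")
    return _ols_with_anova(rows, response, predictors or EXPRESSION_PREDICTORS)


def tile_level_model(
    rows: pd.DataFrame,
    response: str = "cpa_level",
    exclude_cpg_density: bool | None = None,
    predictors: list[str] | None = None,
) -> LinearModelResult:
    """OLS + sequential ANOVA over 1 kb tile features.

    The response's own level column is always excluded from the predictors.
    When predicting CpA methylation, CpG-density-related variables are
    excluded by default (they would otherwise dominate); when predicting CpG
    or CpT methylation, CpA level enters as a predictor.
    """
    if exclude_cpg_density is None:
        exclude_cpg_density = response == "cpa_level"
    preds = list(predictors) if predictors is not None else list(TILE_PREDICTORS)
    if response in ("cpg_level", "cpt_level") and "cpa_level" not in preds:
        preds.append("cpa_level")
    preds = [p for p in preds if p != response]
    if exclude_cpg_density:
        preds = [p for p in preds if p not in CPG_DENSITY_PREDICTORS]
    return _ols_with_anova(rows, response, preds)


def build_tile_features(
    samples: list[SampleTable],
    genome,
    tile_bp: int = 1000,
    min_cov: int = 5,
    min_cpa: int = 2,
    repeats=None,
    h3k36me3=None,
    chrom: str | None = None,
) -> pd.DataFrame:
    """Per-tile feature rows for the tile-level linear models.

    Tiles require >= ``min_cpa`` CpAs covered > ``min_cov`` in all samples.
    Features: A/C/G/T content, repeat content, CpA content, CpA-CpG ratio,
    mean CpC/CpG/CpT levels, H3K36me3 presence (boolean from a BED-style
    interval list) and the mean cross-sample conservation score of the
    tile's CpAs. The response columns are the across-sample mean levels.
    """
    from ._seq import cytosine_table

    seqs = load_genome(genome)
    if chrom is None:
        chrom = next(iter(seqs))
    seq = seqs[chrom]
    n = len(seq)

    lv = {ctx: level_matrix(samples, ctx, min_cov=min_cov).dropna(axis=0, how="any")
          for ctx in ("CpA", "CpG", "CpT", "CpC")}
    cons = conservation_scores(
        samples, [tuple(ix) for ix in lv["CpA"].index], context="CpA",
        min_cov=min_cov, cap=COVERAGE_CAP,
    )
    ct = cytosine_table(seq, chrom)
    dinuc_pos = {ctx: ct.loc[ct["context"] == ctx, "pos0"].to_numpy()
                 for ctx in ("CpA", "CpG")}

    def interval_frac(ivals, ts, te):
        if not ivals:
            return 0.0
        covered = 0
        for s, e in ivals:
            covered += max(0, min(e, te) - max(s, ts))
        return covered / (te - ts)

    rows = []
    for ts in range(0, n - tile_bp + 1, tile_bp):
        te = ts + tile_bp
        window = seq[ts:te]
        cpa_lv = lv["CpA"][
            (lv["CpA"].index.get_level_values("pos0") >= ts)
            & (lv["CpA"].index.get_level_values("pos0") < te)
        ]
        if len(cpa_lv) < min_cpa:
            continue
        row = {"tile_start": ts, "tile_end": te}
        for b in "ACGT":
            row[f"{b.lower()}_content"] = window.count(b) / tile_bp
        n_cpa = int(((dinuc_pos["CpA"] >= ts) & (dinuc_pos["CpA"] < te)).sum())
        n_cpg = int(((dinuc_pos["CpG"] >= ts) & (dinuc_pos["CpG"] < te)).sum())
        row["cpa_content"] = n_cpa / tile_bp
        row["cpg_content"] = n_cpg / tile_bp
        row["cpa_cpg_ratio"] = n_cpa / n_cpg if n_cpg else np.nan
        row["repeat_content"] = interval_frac(
            repeats.intervals if hasattr(repeats, "intervals") else (repeats or []),
            ts, te)
        ivals = (h3k36me3.intervals if hasattr(h3k36me3, "intervals")
                 else (h3k36me3 or []))
        row["h3k36me3"] = float(any(s < te and ts < e for s, e in ivals))
        row["n_cpa_covered"] = len(cpa_lv)
        row["cpa_level"] = float(cpa_lv.mean(axis=1).mean())
        for ctx in ("CpG", "CpT", "CpC"):
            sub = lv[ctx][
                (lv[ctx].index.get_level_values("pos0") >= ts)
                & (lv[ctx].index.get_level_values("pos0") < te)
            ]
            row[f"{ctx.lower()}_level"] = (
                float(sub.mean(axis=1).mean()) if len(sub) else 0.0
            )
        csub = cons[
            (cons.index.get_level_values("pos0") >= ts)
            & (cons.index.get_level_values("pos0") < te)
        ]["score"].dropna()
        row["conservation"] = float(csub.mean()) if len(csub) else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.dropna(subset=["cpa_cpg_ratio"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Site-level classification

#: The 30 per-CpA features, computed on +/-10 bp windows around the C.
#: A documented reconstruction of the published feature set: sequence
#: composition, dinucleotide counts, neighbouring-CpG methylation, distance
#: features, a DNMT3A-preference motif score, cross-sample conservation and
#: coverage, plus the identity of the immediately flanking bases.
SITE_FEATURES = [
    "frac_a", "frac_c", "frac_g", "frac_t", "gc_content",
    "cpg_count", "cpa_count", "cpt_count", "cpc_count",
    "dist_nearest_cpg", "nearest_cpg_level", "nearest_cpg_methylated",
    "n_meth_cpg_window", "mean_cpg_level_window", "motif_score",
    "conservation", "cross_sample_mean", "cross_sample_sd",
    "coverage_focal", "min_coverage",
    "base_m1_A", "base_m1_C", "base_m1_G", "base_m1_T",
    "base_p2_A", "base_p2_C", "base_p2_G", "base_p2_T",
    "repeat_flag", "dist_nearest_cpa",
]

#: Log-odds position weight matrix for the DNMT3A flanking preference
#: (TA C A C-like context around the methylated C), offsets -2..+2.
_DNMT3A_PWM = {
    -2: {"A": 0.1, "C": 0.2, "G": -0.2, "T": 0.4},
    -1: {"A": 0.5, "C": -0.1, "G": -0.3, "T": 0.2},
    2: {"A": -0.1, "C": 0.6, "G": -0.2, "T": 0.1},
}


def _motif_score(seq: str, pos: int, strand: str) -> float:
    score = 0.0
    for off, weights in _DNMT3A_PWM.items():
        p = pos + off if strand == "+" else pos - off
        if 0 <= p < len(seq):
            b = seq[p] if strand == "+" else revcomp(seq[p])
            score += weights.get(b, 0.0)
    return score


def build_site_features(
    samples: list[SampleTable],
    genome,
    focal: int = 0,
    window: int = 10,
    min_cov: int = 15,
    meth_level_cutoff: float = 0.10,
    repeats=None,
) -> pd.DataFrame:
    """Per-CpA feature vectors for classification.

    Restricted to CpAs with coverage >= ``min_cov`` in *all* samples. The
    label column derives from the focal sample's level (methylated iff
    level >= 5% is applied later, at dataset construction). Neighbour-CpG
    features use the focal sample's CpG levels; ``meth_level_cutoff`` is the
    level at which a neighbouring CpG counts as methylated.
    """
    seqs = load_genome(genome)
    chrom = next(iter(seqs))
    seq = seqs[chrom]

    cpa_lv = level_matrix(samples, "CpA", min_cov=min_cov).dropna(axis=0, how="any")
    cpa_cov = coverage_matrix(samples, "CpA").reindex(cpa_lv.index)
    cons = conservation_scores(
        samples, [tuple(ix) for ix in cpa_lv.index], context="CpA",
        min_cov=min_cov,
    )
    focal_id = samples[focal].sample_id
    fdf = samples[focal].df
    cpg_focal = fdf[fdf["context"] == "CpG"].set_index("pos0")["level"]
    cpg_pos = np.sort(cpg_focal.index.to_numpy())
    cpa_pos_all = np.sort(
        fdf.loc[fdf["context"] == "CpA", "pos0"].to_numpy()
    )
    repeat_ivals = (repeats.intervals if hasattr(repeats, "intervals")
                    else (repeats or []))

    rows = []
    for (c, pos, strand) in cpa_lv.index:
        s, e = pos - window, pos + window + 1
        if s < 0 or e > len(seq):
            continue
        win = seq[s:e] if strand == "+" else revcomp(seq[s:e])
        row = {"chrom": c, "pos0": pos, "strand": strand}
        wlen = len(win)
        for b in "ACGT":
            row[f"frac_{b.lower()}"] = win.count(b) / wlen
        row["gc_content"] = (win.count("G") + win.count("C")) / wlen
        for d, key in (("CG", "cpg_count"), ("CA", "cpa_count"),
                       ("CT", "cpt_count"), ("CC", "cpc_count")):
            row[key] = sum(1 for i in range(wlen - 1) if win[i : i + 2] == d)
        # nearest covered CpG in the focal sample
        if len(cpg_pos):
            j = np.searchsorted(cpg_pos, pos)
            cands = [cpg_pos[k] for k in (j - 1, j) if 0 <= k < len(cpg_pos)]
            near = min(cands, key=lambda q: abs(q - pos))
            row["dist_nearest_cpg"] = float(abs(near - pos))
            row["nearest_cpg_level"] = float(cpg_focal.loc[near].max()
                                             if isinstance(cpg_focal.loc[near], pd.Series)
                                             else cpg_focal.loc[near])
        else:
            row["dist_nearest_cpg"] = float(len(seq))
            row["nearest_cpg_level"] = 0.0
        row["nearest_cpg_methylated"] = float(
            row["nearest_cpg_level"] >= meth_level_cutoff
        )
        in_win = cpg_focal[(cpg_focal.index >= s) & (cpg_focal.index < e)]
        row["n_meth_cpg_window"] = float((in_win >= meth_level_cutoff).sum())
        row["mean_cpg_level_window"] = float(in_win.mean()) if len(in_win) else 0.0
        row["motif_score"] = _motif_score(seq, pos, strand)
        row["conservation"] = float(cons.loc[(c, pos, strand), "score"]) if (
            (c, pos, strand) in cons.index and
            np.isfinite(cons.loc[(c, pos, strand), "score"])
        ) else 0.0
        row["cross_sample_mean"] = float(cpa_lv.loc[(c, pos, strand)].mean())
        row["cross_sample_sd"] = float(cpa_lv.loc[(c, pos, strand)].std(ddof=1))
        row["coverage_focal"] = float(cpa_cov.loc[(c, pos, strand), focal_id])
        row["min_coverage"] = float(cpa_cov.loc[(c, pos, strand)].min())
        m1 = pos - 1 if strand == "+" else pos + 1
        p2 = pos + 2 if strand == "+" else pos - 2
        for off, key in ((m1, "base_m1"), (p2, "base_p2")):
            base = seq[off] if 0 <= off < len(seq) else "N"
            if strand == "-":
                base = revcomp(base)
            for b in "ACGT":
                row[f"{key}_{b}"] = float(base == b)
        row["repeat_flag"] = float(any(rs <= pos < re for rs, re in repeat_ivals))
        if len(cpa_pos_all) > 1:
            j = np.searchsorted(cpa_pos_all, pos)
            cands = [cpa_pos_all[k] for k in (j - 1, j, j + 1)
                     if 0 <= k < len(cpa_pos_all) and cpa_pos_all[k] != pos]
            row["dist_nearest_cpa"] = float(min(abs(q - pos) for q in cands))
        else:
            row["dist_nearest_cpa"] = float(len(seq))
        row["level"] = float(cpa_lv.loc[(c, pos, strand), focal_id])
        rows.append(row)
    return pd.DataFrame(rows)


def build_classification_dataset(
    features: pd.DataFrame,
    threshold: float = 0.05,
    seed: int = 0,
    level_col: str = "level",
) -> pd.DataFrame:
    """Balanced labelled dataset: all methylated sites + an equal-sized
    random subsample of unmethylated ones.

    A site is methylated iff its level >= ``threshold`` (5%). If there are
    fewer unmethylated than methylated sites, all are kept and a warning is
    issued. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    labeled = features.assign(label=(features[level_col] >= threshold).astype(int))
    meth = labeled[labeled["label"] == 1]
    unmeth = labeled[labeled["label"] == 0]
    if len(unmeth) < len(meth):
        import warnings
        warnings.warn("fewer unmethylated than methylated sites; keeping all",
                      stacklevel=2)
        sampled = unmeth
    else:
        idx = rng.choice(unmeth.index.to_numpy(), size=len(meth), replace=False)
        sampled = unmeth.loc[np.sort(idx)]
    out = pd.concat([meth, sampled]).sort_index()
    return out.reset_index(drop=True)


@dataclass
class ClassificationResult:
    method: str
    mean_auc: float
    fold_aucs: list[float]
    importance: pd.Series  # logistic/SVM: coefficient z-scores; RF: Gini, max=1


def crossval_classify(
    dataset: pd.DataFrame,
    method: str = "logistic",
    folds: int = 10,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    label_col: str = "label",
) -> ClassificationResult:
    """Stratified k-fold cross-validated AUC plus full-data feature importances.

    ``method`` is one of "logistic", "svm" (linear kernel) or
    "random_forest" (500 trees). Importances come from a model fitted on the
    full training set: coefficient z-scores for logistic regression and
    linear SVM, and mean-decrease-in-Gini rescaled so the largest value is
    exactly 1 for random forests. Features are standardised for the linear
    methods. A degenerate single-class fold triggers a refold with a new
    seed (logged via warning).
    """
    cols = feature_cols or [c for c in SITE_FEATURES if c in dataset.columns]
    X = dataset[cols].to_numpy(float)
    y = dataset[label_col].to_numpy(int)
    if folds > len(y) // 2:
        raise ValueError("folds must be <= n/2")

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    def make_model():
        if method == "logistic":
            return LogisticRegression(max_iter=2000)
        if method == "svm":
            return LinearSVC()
        if method == "random_forest":
            return RandomForestClassifier(n_estimators=500, random_state=seed,
                                          n_jobs=1)
        raise ValueError(f"unknown method {method!r}")

    use_scaled = method in ("logistic", "svm")
    Xf = Xs if use_scaled else X

    for attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        aucs = []
        ok = True
        for train, test in skf.split(Xf, y):
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                ok = False
                break
            model = make_model()
            model.fit(Xf[train], y[train])
            if hasattr(model, "predict_proba"):
                scores = model.predict_proba(Xf[test])[:, 1]
            else:
                scores = model.decision_function(Xf[test])
            aucs.append(roc_auc_score(y[test], scores))
        if ok:
            break
        import warnings
        warnings.warn("degenerate single-class fold; refolding with new seed",
                      stacklevel=2)
    else:
        raise RuntimeError("could not build non-degenerate folds")

    full = make_model()
    full.fit(Xf, y)
    if method == "random_forest":
        imp = full.feature_importances_.astype(float)
        if imp.max() > 0:
            imp = imp / imp.max()
        importance = pd.Series(imp, index=cols, name="gini_rescaled")
    elif method == "logistic":
        # coefficient z-scores from the observed information matrix
        p = full.predict_proba(Xf)[:, 1]
        W = p * (1 - p)
        Xd = np.hstack([np.ones((len(y), 1)), Xf])
        info = Xd.T @ (Xd * W[:, None])
        # pseudo-inverse: one-hot blocks and composition fractions are
        # collinear by construction, making the information matrix singular
        se = np.sqrt(np.abs(np.diag(np.linalg.pinv(info))))[1:]
        se[se == 0] = np.nan
        importance = pd.Series(full.coef_[0] / se, index=cols, name="z_score")
    else:  # svm: z-score of coefficients across features
        coef = full.coef_[0]
        importance = pd.Series(
            (coef - coef.mean()) / (coef.std(ddof=1) or 1.0),
            index=cols, name="z_score",
        )
    return ClassificationResult(
        method=method,
        mean_auc=float(np.mean(aucs)),
        fold_aucs=[float(a) for a in aucs],
        importance=importance,
    )
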