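"""Node-level topology and the group-level multilevel model.

Per patient, the degree and (unnormalized) betweenness centrality of every
node are computed for both networks and compared with Spearman rank
correlations, FDR-corrected across patients.  At group level a linear
multilevel model with a random intercept per patient relates the structural
degree to the effective degree, with node proximity, contact-area volume
(VEA) and seizure-onset-zone membership as candidate confounds; predictors
are pruned by backward elimination.  The intraclass correlation
ICC = sigma2_inter / (sigma2_inter + sigma2_intra) from an intercept-only
model quantifies between-patient dependency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .networks import BinaryNetwork

__all__ = [
    "ModelFit",
    "degree",
    "betweenness_centrality",
    "spearman_with_fdr",
    "build_node_table",
    "fit_intercept_only",
    "fit_multilevel",
    "backward_eliminate",
]

logger = logging.getLogger(__name__)

#: Candidate fixed effects for the group model, in fitting order.
DEFAULT_PREDICTORS = ("ec_degree", "proximity", "vea", "soz")
#: Continuous columns that are z-scored when standardization is on.
CONTINUOUS_COLUMNS = ("sc_degree", "ec_degree", "proximity", "vea")


def degree(net: BinaryNetwork) -> np.ndarray:
    """Node degree: row sums of the symmetric adjacency."""
    return net.adjacency.sum(axis=1).astype(int)


def betweenness_centrality(net: BinaryNetwork) -> np.ndarray:
    """Unnormalized betweenness centrality over unordered node pairs.

    BC(v) = sum over pairs s != t != v of sigma_st(v) / sigma_st with
    sigma_st the number of unweighted shortest paths between s and t;
    disconnected pairs contribute 0.
    """
    g = nx.from_numpy_array(net.adjacency.astype(int))
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(net.n_nodes)])


def spearman_with_fdr(per_patient: dict, q: float = 0.05) -> pd.DataFrame:
    """Per-patient Spearman correlation with Benjamini-Hochberg correction.

    Parameters
    ----------
    per_patient : dict
        Maps patient id -> (x, y) arrays of a node metric in each modality.
    q : float
        FDR level across the family of patients.

    Ties receive average ranks (scipy default); patients with a constant
    vector get rho = NaN and are flagged, not entering the correction.
    """
    rows = []
    for pid, (x, y) in per_patient.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 4:
            raise ValueError(f"patient {pid}: need >= 4 nodes for Spearman")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"patient": pid, "rho": np.nan, "p": np.nan,
                         "constant": True})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"patient": pid, "rho": float(rho), "p": float(p),
                     "constant": False})
    out = pd.DataFrame(rows)
    ok = ~out["constant"]
    out["p_fdr"] = np.nan
    out["significant"] = False
    if ok.any():
        rej, p_adj, _, _ = multipletests(out.loc[ok, "p"], alpha=q,
                                         method="fdr_bh")
        out.loc[ok, "p_fdr"] = p_adj
        out.loc[ok, "significant"] = rej
    return out


def build_node_table(per_patient: dict) -> pd.DataFrame:
    """Assemble the long-format node table for the group model.

    ``per_patient`` maps patient id to a dict with keys ``labels``, ``sc``,
    ``ec`` (BinaryNetwork), ``proximity``, ``vea``, ``soz`` (arrays aligned
    with ``labels``); one row per included node per patient.
    """
    frames = []
    for pid, d in per_patient.items():
        sc, ec = d["sc"], d["ec"]
        if sc.labels != ec.labels:
            raise ValueError(f"patient {pid}: SC/EC node sets differ")
        frames.append(pd.DataFrame({
            "patient": pid,
            "node": list(sc.labels),
            "sc_degree": degree(sc),
            "ec_degree": degree(ec),
            "proximity": np.asarray(d["proximity"], dtype=float),
            "vea": np.asarray(d["vea"], dtype=float),
            "soz": np.asarray(d["soz"], dtype=float),
            "sc_betweenness": betweenness_centrality(sc),
            "ec_betweenness": betweenness_centrality(ec),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class ModelFit:
    """Fixed effects, variance components and fit summaries of a mixed model."""

    terms: pd.DataFrame  # index: term; beta, se, t, df, p, ci_low, ci_high
    sigma2_inter: float
    sigma2_intra: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    retained: tuple = ()
    elimination_path: list = field(default_factory=list)
    n_obs: int = 0
    n_groups: int = 0
    converged: bool = True
    all_eliminated: bool = False

    def to_dict(self) -> dict:
        return {
            "terms": self.terms.reset_index().to_dict(orient="records"),
            "sigma2_inter": self.sigma2_inter,
            "sigma2_intra": self.sigma2_intra,
            "icc": self.icc,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "retained": list(self.retained),
            "elimination_path": self.elimination_path,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "all_eliminated": self.all_eliminated,
        }


def _prepare(table, outcome, predictors, standardize):
    df = table.copy()
    if "soz" in predictors:
        # drop patients without a delineated SOZ from SOZ-containing fits
        bad = df.groupby("patient")["soz"].apply(lambda s: s.isna().all())
        drop = bad[bad].index
        if len(drop):
            logger.info("dropping %d patients without delineated SOZ", len(drop))
            df = df[~df["patient"].isin(drop)]
    df = df.dropna(subset=[outcome, *predictors])
    if standardize:
        for col in {outcome, *predictors} & set(CONTINUOUS_COLUMNS):
            v = df[col].to_numpy(dtype=float)
            sd = v.std()
            if sd == 0:
                raise ValueError(f"column {col!r} is constant; cannot standardize")
            df[col] = (v - v.mean()) / sd
    return df


def _mixedlm_fit(df, outcome, predictors):
    exog = pd.DataFrame({"Intercept": np.ones(len(df))})
    for p in predictors:
        exog[p] = df[p].to_numpy(dtype=float)
    model = MixedLM(df[outcome].to_numpy(dtype=float), exog,
                    groups=df["patient"].to_numpy())
    with np.errstate(all="ignore"):
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError:
            # gradient methods can fail when the random-intercept variance
            # sits on the boundary; Powell is derivative-free and robust there
            res = model.fit(reml=True, method="powell")
    return res, exog


def _summarize(res, exog, df, predictors) -> ModelFit:
    n = len(df)
    n_groups = df["patient"].nunique()
    k_fe = exog.shape[1]
    ddf = max(n - k_fe - n_groups, 1)  # residual df, matching t(n - p - groups)
    beta = res.fe_params
    se = res.bse_fe
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), ddf)
    tcrit = stats.t.ppf(0.975, ddf)
    terms = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t": t,
            "df": float(ddf),
            "p": p,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
        }
    )
    sigma2_inter = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
    sigma2_intra = float(res.scale)
    icc = sigma2_inter / (sigma2_inter + sigma2_intra)
    # variance of the fixed-effect linear predictor (Nakagawa R^2)
    fixed_pred = exog.to_numpy() @ beta.to_numpy()
    var_f = float(np.var(fixed_pred))
    total = var_f + sigma2_inter + sigma2_intra
    return ModelFit(
        terms=terms,
        sigma2_inter=sigma2_inter,
        sigma2_intra=sigma2_intra,
        icc=icc,
        r2_marginal=var_f / total,
        r2_conditional=(var_f + sigma2_inter) / total,
        retained=tuple(predictors),
        n_obs=n,
        n_groups=n_groups,
        converged=bool(res.converged),
    )


def fit_intercept_only(table: pd.DataFrame, outcome: str = "sc_degree",
                       standardize: bool = True) -> ModelFit:
    """Random-intercept-only REML fit quantifying between-patient dependency.

    The ICC is the share of outcome variance attributable to stable
    between-patient differences.
    """
    if table["patient"].nunique() < 2:
        raise ValueError("intercept-only model requires >= 2 patients")
    df = _prepare(table, outcome, (), standardize)
    res, exog = _mixedlm_fit(df, outcome, ())
    return _summarize(res, exog, df, ())


def fit_multilevel(
    table: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    outcome: str = "sc_degree",
    standardize: bool = True,
) -> ModelFit:
    """Random-intercept linear multilevel model of a node metric.

    Outcome and continuous predictors are z-scored over all pooled rows when
    ``standardize`` is on (the binary SOZ flag is left as is); the model is
    fit by REML with one random intercept per patient.  Wald t statistics use
    residual degrees of freedom n - p - n_patients; confidence intervals are
    t-based at 95%.
    """
    predictors = tuple(predictors)
    unknown = set(predictors) - set(table.columns)
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    if table["patient"].nunique() < 2:
        raise ValueError("multilevel model requires >= 2 patients")
    df = _prepare(table, outcome, predictors, standardize)
    res, exog = _mixedlm_fit(df, outcome, predictors)
    if not res.converged:
        logger.warning("mixed model did not converge; inspect diagnostics")
    return _summarize(res, exog, df, predictors)


def backward_eliminate(
    table: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    outcome: str = "sc_degree",
    alpha: float = 0.05,
    standardize: bool = True,
) -> ModelFit:
    """Iteratively drop the least-significant predictor until all are significant.

    At each step the predictor with the largest p-value above ``alpha`` is
    removed and the model refit; the path of removals is recorded.  If every
    predictor is eliminated, the intercept-only fit is returned flagged.
    """
    remaining = list(predictors)
    path = []
    while remaining:
        fit = fit_multilevel(table, remaining, outcome, standardize)
        pvals = fit.terms.loc[remaining, "p"]
        worst = pvals.idxmax()
        if pvals[worst] <= alpha:
            fit.elimination_path = path
            return fit
        path.append({"dropped": worst, "p": float(pvals[worst]),
                     "model": list(remaining)})
        remaining.remove(worst)
    fit = fit_intercept_only(table, outcome, standardize)
    fit.elimination_path = path
    fit.all_eliminated = True
    logger.warning("backward elimination removed every predictor")
    return fit
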