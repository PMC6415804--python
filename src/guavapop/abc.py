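"""Approximate Bayesian Computation over colonisation scenarios.

A reference table of (scenario, parameter draw, summary statistics) rows is
simulated under every demographic scenario; the observed dataset is reduced
to the same summaries (per-population mean allele number and mean gene
diversity, pairwise F_ST); rejection keeps the closest rows under a
MAD-normalised Euclidean distance; scenario posterior probabilities come
from an Epanechnikov-weighted multinomial logistic regression of the
scenario indicator on the summary deviations (evaluated at deviation 0),
and parameter posteriors from Beaumont-style weighted local-linear
regression adjustment on a log scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guavapop.coalsim import MutationModel, PriorSpec, simulate_dataset
from guavapop.diversity import gene_diversity
from guavapop.genotypes import MISSING, GenotypeMatrix
from guavapop.structure_stats import pairwise_fst

logger = logging.getLogger(__name__)


def summary_names(pop_names=("ISA", "SCZ", "SCY")) -> list:
    a, b, c = pop_names
    return [f"A_{a}", f"A_{b}", f"A_{c}",
            f"H_{a}", f"H_{b}", f"H_{c}",
            f"FST_{a}_{b}", f"FST_{a}_{c}", f"FST_{b}_{c}"]


def summarize(gm: GenotypeMatrix) -> np.ndarray:
    """Summary vector: per-pop mean allele count and mean gene diversity
    across loci, then the three pairwise F_ST values, in fixed pop order."""
    pops = gm.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    a_means, h_means = [], []
    for p in pops:
        sub = gm.alleles[gm.pop == p]
        counts = []
        for j in range(gm.n_loci):
            copies = sub[:, j, :].ravel()
            copies = copies[copies != MISSING]
            counts.append(np.unique(copies).size)
        a_means.append(float(np.mean(counts)))
        _, h = gene_diversity(gm, p)
        h_means.append(h)
    fst = pairwise_fst(gm)
    pairs = [(i, j) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    # monomorphic comparisons have an empty theta denominator; the
    # conventional summary value is zero differentiation
    fst_vals = [v if np.isfinite(v) else 0.0
                for v in (fst.values[i, j] for i, j in pairs)]
    return np.asarray(a_means + h_means + fst_vals)


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summaries) records plus metadata."""

    data: pd.DataFrame
    stat_cols: list
    param_cols: list
    metadata: dict = field(default_factory=dict)

    def scale(self) -> np.ndarray:
        """Per-statistic MAD (falling back to sd, then 1) for normalisation."""
        x = self.data[self.stat_cols].to_numpy()
        mad = np.median(np.abs(x - np.median(x, axis=0)), axis=0)
        sd = x.std(axis=0)
        out = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
        return out

    def to_csv(self, path, sep="\t"):
        with open(path, "w") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            self.data.to_csv(fh, sep=sep, index=False)


def build_reference_table(scenarios, prior_spec: PriorSpec, n_per_scenario: int,
                          sample_sizes=(95, 80, 94), n_loci: int = 11,
                          mut_model: MutationModel | None = None,
                          seed: int = 0, normalization: str = "mad",
                          checkpoint=None) -> ReferenceTable:
    """Simulate the ABC reference table (scenario-major row order).

    Fully reproducible from seed: every row derives its generator from
    (seed, scenario index, row index). Rows with non-finite summaries are
    dropped and logged. With *checkpoint* (a path), completed rows are
    flushed to a TSV periodically and a later call resumes after the rows
    already present.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    model = mut_model or MutationModel(rate_range=(1e-4, 1e-3))
    param_names = sorted({n for s in scenarios for n in s.parameter_names()})
    stat_cols = summary_names(scenarios[0].pop_names)
    rows = []
    done = set()
    if checkpoint is not None:
        from pathlib import Path

        checkpoint = Path(checkpoint)
        if checkpoint.exists():
            prev = pd.read_csv(checkpoint, sep="\t")
            rows = prev.to_dict("records")
            done = set(zip(prev["scenario"], prev["rep"]))
            logger.info("resuming reference table: %d rows checkpointed", len(rows))

    def flush():
        pd.DataFrame(rows).to_csv(checkpoint, sep="\t", index=False)

    dropped = 0
    since_flush = 0
    for si, scen in enumerate(scenarios):
        for row in range(n_per_scenario):
            if (scen.id, row) in done:
                continue
            rng = np.random.default_rng([seed, si, row])
            params = prior_spec.sample(scen, rng)
            gm = simulate_dataset(scen, params, sample_sizes, n_loci, model, rng)
            s = summarize(gm)
            if not np.all(np.isfinite(s)):
                dropped += 1
                logger.warning("dropping non-finite summary row (scenario %s)", scen.id)
                continue
            rec = {"scenario": scen.id, "rep": row}
            rec.update({n: params.get(n, np.nan) for n in param_names})
            rec.update(dict(zip(stat_cols, s)))
            rows.append(rec)
            since_flush += 1
            if checkpoint is not None and since_flush >= 200:
                flush()
                since_flush = 0
    if checkpoint is not None and since_flush:
        flush()
    df = pd.DataFrame(rows).sort_values(["scenario", "rep"],
                                        kind="stable").reset_index(drop=True)
    meta = dict(seed=seed, n_per_scenario=n_per_scenario,
                sample_sizes=tuple(sample_sizes), n_loci=n_loci,
                mutation=f"{model.kind} rate={model.rate} range={model.rate_range}",
                priors=str(prior_spec), normalization=normalization,
                n_rows=len(df), dropped=dropped)
    return ReferenceTable(data=df, stat_cols=stat_cols,
                          param_cols=param_names, metadata=meta)


def rejection(ref: ReferenceTable, observed: np.ndarray, tolerance: float = 0.01,
              min_retained: int = 500) -> pd.DataFrame:
    """Retain the ceil(tolerance * rows) reference rows closest to the
    observation (Euclidean distance on MAD-normalised summaries), with a
    floor of min_retained rows. Adds a 'distance' column."""
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    scale = ref.scale()
    x = ref.data[ref.stat_cols].to_numpy() / scale
    obs = np.asarray(observed) / scale
    d = np.sqrt(((x - obs) ** 2).sum(axis=1))
    if not np.isfinite(d).any():
        raise ValueError("all distances are non-finite")
    n_keep = min(len(d), max(math.ceil(tolerance * len(d)), min_retained))
    idx = np.argsort(d, kind="stable")[:n_keep]
    out = ref.data.iloc[idx].copy()
    out["distance"] = d[idx]
    out.attrs["scale"] = scale
    out.attrs["stat_cols"] = ref.stat_cols
    return out


@dataclass
class AbcModelChoice:
    probabilities: dict             # scenario id -> posterior probability
    retained_counts: dict
    tolerance: float
    method: str = "logistic"

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")

    def best(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max() * (1 + 1e-9) if d.max() > 0 else 1.0
    return 1.0 - (d / dmax) ** 2


def model_posterior_logistic(retained: pd.DataFrame, observed: np.ndarray,
                             tolerance: float = np.nan) -> AbcModelChoice:
    """Scenario posterior probabilities by weighted multinomial logistic
    regression of the scenario label on (summaries - observed), evaluated
    at deviation zero. Falls back to retained-count proportions (flagged in
    `method`) when the regression is degenerate."""
    stat_cols = retained.attrs.get("stat_cols")
    scale = retained.attrs.get("scale")
    labels = retained["scenario"].to_numpy()
    classes = sorted(set(labels))
    counts = {c: int((labels == c).sum()) for c in classes}
    if len(classes) == 1:
        logger.warning("single scenario among retained rows")
        return AbcModelChoice(probabilities={classes[0]: 1.0},
                              retained_counts=counts, tolerance=tolerance,
                              method="single-class")
    x = retained[stat_cols].to_numpy() / scale - np.asarray(observed) / scale
    w = _epanechnikov(retained["distance"].to_numpy())
    try:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e6, max_iter=2000)
        clf.fit(x, labels, sample_weight=w)
        probs = clf.predict_proba(np.zeros((1, x.shape[1])))[0]
        prob_map = dict(zip(clf.classes_, probs))
        method = "logistic"
    except Exception as exc:  # degenerate fit
        logger.warning("logistic model choice degenerate (%s); using proportions", exc)
        total = sum(counts.values())
        prob_map = {c: counts[c] / total for c in classes}
        method = "rejection-proportions"
    total = sum(prob_map.values())
    prob_map = {c: float(p / total) for c, p in prob_map.items()}
    return AbcModelChoice(probabilities=prob_map, retained_counts=counts,
                          tolerance=tolerance, method=method)


@dataclass
class ParamPosterior:
    """Adjusted posterior draws and summaries per parameter."""

    draws: pd.DataFrame
    summary: pd.DataFrame
    adjusted: bool = True


def param_posterior_loclinear(retained: pd.DataFrame, observed: np.ndarray,
                              parameter_names: list) -> ParamPosterior:
    """Local-linear regression adjustment of retained parameter draws.

    Each parameter is regressed (weighted least squares, Epanechnikov
    weights in distance) on the normalised summary deviations; adjusted
    draws are intercept + residuals. Positive parameters are adjusted on a
    log scale and back-transformed. A rank-deficient regression returns
    the unadjusted rejection posterior, flagged."""
    stat_cols = retained.attrs.get("stat_cols")
    scale = retained.attrs.get("scale")
    x = retained[stat_cols].to_numpy() / scale - np.asarray(observed) / scale
    w = _epanechnikov(retained["distance"].to_numpy())
    design = np.column_stack([np.ones(len(x)), x])
    sw = np.sqrt(w)
    adjusted = True
    out = {}
    for name in parameter_names:
        theta = retained[name].to_numpy(dtype=float)
        work = np.log(theta) if (theta > 0).all() else theta
        try:
            beta, _, rank, _ = np.linalg.lstsq(design * sw[:, None],
                                               work * sw, rcond=None)
            if rank < design.shape[1]:
                raise np.linalg.LinAlgError("rank deficient")
            adj = beta[0] + (work - design @ beta)
        except np.linalg.LinAlgError:
            logger.warning("loclinear adjustment degenerate for %s; "
                           "returning rejection posterior", name)
            adj = work
            adjusted = False
        out[name] = np.exp(adj) if (theta > 0).all() else adj
    draws = pd.DataFrame(out)
    summary = draws.describe(percentiles=[0.025, 0.5, 0.975]).T[
        ["mean", "2.5%", "50%", "97.5%"]]
    summary.columns = ["mean", "q2.5", "median", "q97.5"]
    return ParamPosterior(draws=draws, summary=summary, adjusted=adjusted)


def generations_since(year_start: int, year_end: int, generation_time: float) -> int:
    """Number of whole generations in a historical interval."""
    if year_end <= year_start:
        raise ValueError("year_end must exceed year_start")
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    return int(math.floor((year_end - year_start) / generation_time))
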