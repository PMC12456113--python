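"""ABC random-forest model choice and parameter estimation.

The reference table (one row per simulated dataset: scenario label,
parameter draw, summary-statistic vector) trains a 500-tree classification
forest for scenario choice.  The posterior probability of the selected
scenario follows the ABC-RF error-regression construction: a second forest
regresses the out-of-bag misclassification indicator on the statistics and
the posterior is one minus its prediction at the observed point.  Parameter
estimation uses one regression forest per parameter with leaf co-occurrence
weights, giving weighted-median point estimates, weighted 2.5/97.5%
credible bounds, an out-of-bag normalised MAE and a local posterior RMSE.

Model/results layout: :class:`ScenarioChoice` and :class:`ParameterRegression`
are built from a :class:`ReferenceTable` plus an observed vector, and their
``fit()`` returns a results object with estimates, uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalsim import simulate_dataset
from .scenarios import Scenario, sample_parameters
from .sumstats import SumStatConfig, summary_vector

__all__ = [
    "ReferenceTable",
    "build_reference_table",
    "append_lda_features",
    "ScenarioChoice",
    "ScenarioChoiceResults",
    "ParameterRegression",
    "ParameterEstimationResults",
    "ParamEstimate",
    "hierarchical_run",
]

PARAM_PREFIX = "param_"
STAT_PREFIX = "stat_"


@dataclass
class ReferenceTable:
    """Simulated training data: scenario labels, parameter draws, statistics.

    Statistic columns are fully finite — non-finite simulation outputs are
    imputed with the per-column training mean and flagged by a companion
    ``miss_`` indicator column (itself used as a forest feature).
    """

    data: pd.DataFrame
    stat_names: list[str]

    def __post_init__(self) -> None:
        stats = self.data[self.feature_columns]
        if not np.isfinite(stats.to_numpy()).all():
            raise ValueError("reference table contains non-finite statistics; "
                             "impute before constructing")

    @property
    def scenario_ids(self) -> list[str]:
        return list(pd.unique(self.data["scenario_id"]))

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns
                if c.startswith((STAT_PREFIX, "miss_", "lda_"))]

    @property
    def parameter_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(PARAM_PREFIX)]

    def features(self) -> np.ndarray:
        return self.data[self.feature_columns].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.data["scenario_id"].to_numpy()

    def restrict(self, scenario_ids) -> "ReferenceTable":
        keep = self.data["scenario_id"].isin(list(scenario_ids))
        return ReferenceTable(self.data.loc[keep].reset_index(drop=True),
                              list(self.stat_names))

    def observed_row(self, stats: np.ndarray) -> np.ndarray:
        """Align a raw summary vector with the table's feature columns.

        Non-finite entries are imputed with the training mean of that
        statistic; indicator and LDA columns are filled accordingly.
        """
        stats = np.asarray(stats, dtype=float)
        if stats.shape[0] != len(self.stat_names):
            raise ValueError("observed vector length does not match the table")
        values: dict[str, float] = {}
        for name, x in zip(self.stat_names, stats):
            col = STAT_PREFIX + name
            if np.isfinite(x):
                values[col] = x
            else:
                values[col] = float(self.data[col].mean())
            if f"miss_{name}" in self.data.columns:
                values[f"miss_{name}"] = float(not np.isfinite(x))
        row = []
        for c in self.feature_columns:
            if c.startswith("lda_"):
                raise ValueError("table has LDA features; use append_lda_features "
                                 "to project the observed vector")
            row.append(values[c])
        return np.asarray(row)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        data = pd.read_csv(path, sep="\t")
        stat_names = [c[len(STAT_PREFIX):] for c in data.columns
                      if c.startswith(STAT_PREFIX)]
        return cls(data, stat_names)


def build_reference_table(scenarios: list[Scenario], n_per_scenario: int,
                          n_loci: int, maf: float = 0.025,
                          missing_rate: float = 0.0, seed: int = 0,
                          config: SumStatConfig | None = None,
                          progress: bool = False) -> ReferenceTable:
    """Simulate the training table: equal allocation across scenarios.

    Per row: draw parameters from the scenario's joint prior, simulate a SNP
    dataset, compute the summary vector.  Seeds derive deterministically from
    ``seed``; the whole table is a pure function of its arguments.
    """
    if config is None:
        roster = scenarios[0].sampled_populations
        config = SumStatConfig.default([p.name for p in roster])
    stat_names = config.names()
    rng = np.random.default_rng(seed)
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        if progress:
            import logging
            logging.getLogger(__name__).info(
                "simulating %d datasets under %s", n_per_scenario,
                scenario.scenario_id)
        draws = sample_parameters(scenario, n_per_scenario, seed=int(rng.integers(2**31 - 1)))
        sim_seeds = rng.integers(0, 2**31 - 1, size=n_per_scenario)
        for draw, sim_seed in zip(draws, sim_seeds):
            g = simulate_dataset(scenario, draw, n_loci, maf=maf,
                                 missing_rate=missing_rate, seed=int(sim_seed))
            stats = summary_vector(g, config)
            row = {"scenario_id": scenario.scenario_id, "sim_seed": int(sim_seed)}
            row.update({PARAM_PREFIX + k: v for k, v in draw.values.items()})
            row.update({STAT_PREFIX + k: v for k, v in zip(stat_names, stats)})
            rows.append(row)
    data = pd.DataFrame(rows)
    # union of parameter columns across scenarios -> NaN for absent params is
    # fine (they are never forest features); statistics must be imputed.
    for name in stat_names:
        col = STAT_PREFIX + name
        bad = ~np.isfinite(data[col].to_numpy())
        if bad.any():
            fill = data.loc[~bad, col].mean()
            if not np.isfinite(fill):
                fill = 0.0
            data[f"miss_{name}"] = bad.astype(float)
            data.loc[bad, col] = fill
    return ReferenceTable(data, stat_names)


# ---------------------------------------------------------------------------
# LDA overlap diagnostic

def append_lda_features(rt: ReferenceTable, observed: np.ndarray,
                        jitter: float = 1e-8):
    """Fit linear discriminant axes on scenario labels; append projections.

    Returns (augmented table, projected observed vector, axis loadings).
    The within-class covariance is ridge-regularised with a fixed small
    shrinkage so singular tables never fail.  At most n_scenarios - 1 axes.
    """
    if len(rt.scenario_ids) < 2:
        raise ValueError("LDA needs at least two scenarios")
    observed = np.asarray(observed, dtype=float)
    squeeze = observed.ndim == 1
    obs_rows = np.stack([rt.observed_row(o)
                         for o in np.atleast_2d(observed)])
    X = rt.features()
    y = rt.labels()
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=jitter)
    proj = lda.fit(X, y).transform(X)
    obs_proj = lda.transform(obs_rows)
    data = rt.data.copy()
    for k in range(proj.shape[1]):
        data[f"lda_{k}"] = proj[:, k]
    augmented = ReferenceTable(data, list(rt.stat_names))
    obs_aug = np.hstack([obs_rows, obs_proj])
    return augmented, (obs_aug[0] if squeeze else obs_aug), lda.scalings_


# ---------------------------------------------------------------------------
# scenario choice

@dataclass
class ScenarioChoiceResults:
    """Votes, selection, posterior probability and error rates."""

    scenario_ids: list[str]
    votes: dict[str, int]
    selected: str
    posterior: float
    prior_error: float
    local_error: float
    tie: bool
    n_trees: int
    model: "ScenarioChoice" = field(repr=False)

    def summary(self) -> str:
        lines = ["ABC-RF scenario choice", "=" * 38]
        lines.append(f"{'scenario':<16}{'votes':>8}{'fraction':>10}")
        for s in self.scenario_ids:
            v = self.votes[s]
            lines.append(f"{s:<16}{v:>8}{v / self.n_trees:>10.3f}")
        lines.append("-" * 38)
        flag = "  (tie: lowest index taken)" if self.tie else ""
        lines.append(f"selected scenario : {self.selected}{flag}")
        lines.append(f"posterior P       : {self.posterior:.3f}")
        lines.append(f"prior error (OOB) : {self.prior_error:.3f}")
        lines.append(f"local error       : {self.local_error:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "votes": self.votes, "selected": self.selected,
            "posterior": self.posterior, "prior_error": self.prior_error,
            "local_error": self.local_error, "tie": self.tie,
            "n_trees": self.n_trees,
        }

    def classify(self, observed_row: np.ndarray) -> "ScenarioChoiceResults":
        """Classify another observed point with the already-fitted forests."""
        return self.model._classify(observed_row, self.prior_error)


class ScenarioChoice:
    """Random-forest model choice over a reference table.

    Parameters
    ----------
    reference_table : ReferenceTable
    observed : observed summary vector (raw statistic order) or aligned
        feature row; raw vectors are aligned/imputed automatically.
    n_trees : trees in both the choice and the error-regression forest.
    seed : controls both forests.
    """

    def __init__(self, reference_table: ReferenceTable, observed: np.ndarray,
                 n_trees: int = 500, seed: int = 0):
        self.reference_table = reference_table
        self.observed = np.asarray(observed, dtype=float)
        self.n_trees = n_trees
        self.seed = seed
        ids = reference_table.scenario_ids
        if len(ids) < 2:
            raise ValueError("model choice needs at least two scenarios")
        counts = reference_table.data["scenario_id"].value_counts()
        if (counts < 50).any():
            raise ValueError("need at least 50 rows per scenario")

    def _observed_row(self) -> np.ndarray:
        if self.observed.shape[0] == len(self.reference_table.feature_columns):
            return self.observed
        return self.reference_table.observed_row(self.observed)

    def fit(self) -> ScenarioChoiceResults:
        rt = self.reference_table
        X = rt.features()
        y = rt.labels()
        clf = RandomForestClassifier(
            n_estimators=self.n_trees, oob_score=True, bootstrap=True,
            random_state=self.seed, n_jobs=1)
        clf.fit(X, y)
        prior_error = 1.0 - clf.oob_score_

        # Pudlo-style posterior machinery: regress the OOB misclassification
        # indicator on the features once; the prediction at any observed
        # point is its local error.  Independent of the observed vector.
        oob_pred = clf.classes_[np.argmax(clf.oob_decision_function_, axis=1)]
        misclassified = (oob_pred != y).astype(float)
        # min_samples_leaf smooths the error surface: the prediction at a
        # single point otherwise inherits the variance of a handful of
        # nearest training rows shared across trees
        err_rf = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.seed + 1,
            min_samples_leaf=10, n_jobs=1)
        err_rf.fit(X, misclassified)
        self.classifier_ = clf
        self.error_forest_ = err_rf
        return self._classify(self._observed_row(), float(prior_error))

    def _classify(self, obs_row: np.ndarray,
                  prior_error: float) -> ScenarioChoiceResults:
        rt = self.reference_table
        clf = self.classifier_
        obs = np.asarray(obs_row, dtype=float).reshape(1, -1)
        # sub-estimators predict in encoded class-index space
        per_tree = np.array([t.predict(obs)[0] for t in clf.estimators_])
        tree_labels = clf.classes_[per_tree.astype(int)]
        ids = sorted(rt.scenario_ids)
        votes = {s: int(np.sum(tree_labels == s)) for s in ids}
        best = max(votes.values())
        winners = [s for s in ids if votes[s] == best]
        selected, tie = winners[0], len(winners) > 1
        local_error = float(np.clip(self.error_forest_.predict(obs)[0], 0.0, 1.0))
        posterior = float(np.clip(1.0 - local_error, 0.0, 1.0))
        return ScenarioChoiceResults(
            scenario_ids=ids, votes=votes, selected=selected,
            posterior=posterior, prior_error=prior_error,
            local_error=local_error, tie=tie, n_trees=self.n_trees, model=self)


# ---------------------------------------------------------------------------
# parameter estimation

@dataclass
class ParamEstimate:
    name: str
    point: float       # weighted median
    ci_low: float      # weighted 2.5% quantile
    ci_high: float     # weighted 97.5% quantile
    nmae: float        # out-of-bag mean |error| / mean |truth|
    post_rmse: float   # weighted RMS deviation from the weighted median

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError(f"inconsistent credible interval for {self.name}")


def _weighted_quantile(values: np.ndarray, weights: np.ndarray,
                       q: np.ndarray) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return np.interp(q, cdf, v)


@dataclass
class ParameterEstimationResults:
    scenario_id: str
    estimates: list[ParamEstimate]
    weights: np.ndarray = field(repr=False)
    model: "ParameterRegression" = field(repr=False, default=None)

    def estimate(self, observed: np.ndarray) -> "ParameterEstimationResults":
        """Estimate for another observed point with the fitted forests."""
        return self.model._estimate(observed)

    def __getitem__(self, name: str) -> ParamEstimate:
        for e in self.estimates:
            if e.name == name:
                return e
        raise KeyError(name)

    def summary(self) -> str:
        lines = [f"ABC-RF parameter estimates ({self.scenario_id})", "=" * 74]
        lines.append(f"{'parameter':<20}{'median':>12}{'2.5%':>12}{'97.5%':>12}"
                     f"{'NMAE':>8}{'RMSE':>10}")
        for e in self.estimates:
            lines.append(f"{e.name:<20}{e.point:>12.4g}{e.ci_low:>12.4g}"
                         f"{e.ci_high:>12.4g}{e.nmae:>8.3f}{e.post_rmse:>10.4g}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "parameter": e.name, "point": e.point, "ci_low": e.ci_low,
            "ci_high": e.ci_high, "nmae": e.nmae, "post_rmse": e.post_rmse,
        } for e in self.estimates])


class ParameterRegression:
    """Per-parameter regression forests with leaf co-occurrence weights.

    The table must be restricted to a single scenario.  For each parameter a
    forest maps statistics to the parameter; training rows sharing a leaf
    with the observed point (averaged over trees, normalised by leaf size)
    provide posterior weights for the weighted median / credible interval.
    """

    def __init__(self, reference_table: ReferenceTable, observed: np.ndarray,
                 parameters: list[str] | None = None, n_trees: int = 500,
                 seed: int = 0, min_rows: int = 500):
        if len(reference_table.scenario_ids) != 1:
            raise ValueError("restrict the table to the chosen scenario first")
        if len(reference_table.data) < min_rows:
            raise ValueError(f"need at least {min_rows} rows for estimation")
        self.reference_table = reference_table
        self.observed = np.asarray(observed, dtype=float)
        if parameters is None:
            parameters = [c[len(PARAM_PREFIX):]
                          for c in reference_table.parameter_columns]
        self.parameters = parameters
        self.n_trees = n_trees
        self.seed = seed

    def fit(self) -> ParameterEstimationResults:
        rt = self.reference_table
        X = rt.features()
        self.forests_ = {}
        self._train_leaves = {}
        for k, name in enumerate(self.parameters):
            y = rt.data[PARAM_PREFIX + name].to_numpy(dtype=float)
            if np.isnan(y).any():
                raise ValueError(f"parameter {name!r} missing for some rows")
            rf = RandomForestRegressor(
                n_estimators=self.n_trees, oob_score=True,
                random_state=self.seed + k, n_jobs=1)
            rf.fit(X, y)
            self.forests_[name] = rf
            self._train_leaves[name] = rf.apply(X)  # (n, trees)
        return self._estimate(self.observed)

    def _estimate(self, observed: np.ndarray) -> ParameterEstimationResults:
        rt = self.reference_table
        obs = np.asarray(observed, dtype=float)
        if obs.shape[0] != len(rt.feature_columns):
            obs = rt.observed_row(obs)
        obs = obs.reshape(1, -1)
        estimates = []
        weights_out = None
        for name in self.parameters:
            rf = self.forests_[name]
            y = rt.data[PARAM_PREFIX + name].to_numpy(dtype=float)
            leaves = self._train_leaves[name]
            obs_leaves = rf.apply(obs)[0]      # (trees,)
            w = np.zeros(len(y))
            for t in range(leaves.shape[1]):
                mask = leaves[:, t] == obs_leaves[t]
                n_in = mask.sum()
                if n_in:
                    w[mask] += 1.0 / n_in
            total = w.sum()
            if total <= 0:
                raise ValueError(f"zero posterior weight for parameter {name!r}")
            w /= total
            point, lo, hi = _weighted_quantile(y, w, np.array([0.5, 0.025, 0.975]))
            denom = np.mean(np.abs(y))
            nmae = float(np.mean(np.abs(rf.oob_prediction_ - y)) / denom) \
                if denom > 0 else 0.0
            post_rmse = float(np.sqrt(np.sum(w * (y - point) ** 2)))
            estimates.append(ParamEstimate(name, float(point), float(lo),
                                           float(hi), nmae, post_rmse))
            weights_out = w
        return ParameterEstimationResults(rt.scenario_ids[0], estimates,
                                          weights_out, model=self)


# ---------------------------------------------------------------------------
# hierarchical (staged) model testing

@dataclass
class Stage:
    name: str
    reference_table: ReferenceTable
    observed: np.ndarray


@dataclass
class StageReport:
    name: str
    choice: ScenarioChoiceResults
    passed: bool


@dataclass
class HierarchicalReport:
    stages: list[StageReport]
    halted_at: str | None
    estimates: ParameterEstimationResults | None

    @property
    def completed(self) -> bool:
        return self.halted_at is None


def hierarchical_run(stages: list[Stage], n_trees: int = 500, seed: int = 0,
                     posterior_threshold: float = 0.65,
                     local_error_threshold: float = 0.20,
                     estimate_final: bool = True,
                     min_rows_estimation: int = 500) -> HierarchicalReport:
    """Staged model testing: classify per stage; halt below threshold.

    A stage passes when the selected scenario's posterior reaches the
    posterior threshold and its local error stays at or below the local
    error threshold.  The final passing stage feeds parameter estimation for
    its winning scenario.
    """
    reports: list[StageReport] = []
    estimates = None
    for stage in stages:
        res = ScenarioChoice(stage.reference_table, stage.observed,
                             n_trees=n_trees, seed=seed).fit()
        passed = (res.posterior >= posterior_threshold
                  and res.local_error <= local_error_threshold)
        reports.append(StageReport(stage.name, res, passed))
        if not passed:
            return HierarchicalReport(reports, stage.name, None)
    if estimate_final and reports:
        last_stage = stages[-1]
        winner = reports[-1].choice.selected
        restricted = last_stage.reference_table.restrict([winner])
        estimates = ParameterRegression(
            restricted, last_stage.observed, n_trees=n_trees, seed=seed,
            min_rows=min_rows_estimation).fit()
    return HierarchicalReport(reports, None, estimates)
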