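"""Discovery of differentially methylated CpGs and candidate CpG islands.

The discovery cascade operates on a 450K-style beta-value matrix (probes x
samples, values in [0,1]) labeled PRAD (prostate, normal + cancer) versus
REST (all other benign tissue and blood):

1. drop probes with any missing value;
2. per-probe group mean betas;
3. threshold rule: hypermethylated DMC if mean PRAD beta > 0.75 and mean
   REST beta < 0.25; hypomethylated if mean PRAD < 0.25 and mean REST >
   0.75 (strict inequalities);
4. restrict to probes mapping to CpG islands;
5. recursive feature elimination under repeated stratified cross-validation
   to rank the DMCs by how well they separate the groups;
6. keep CpG islands containing more than one unique DMC, flagging whether
   the member probes agree in direction.

Step 6 groups the full threshold-passing DMC set; RFE contributes the
per-probe rank (and a separately reported accuracy-optimal subset) rather
than pre-filtering the islands, so a single perfectly separating probe
cannot erase its island.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

PRAD = "PRAD"
REST = "REST"

HYPER_HI_DEFAULT = 0.75
LO_DEFAULT = 0.25


@dataclass
class BetaMatrix:
    """Probes x samples beta values with group labels.

    ``values`` is a float DataFrame (probes in rows); missing beta values are
    NaN.  ``labels`` maps every sample to PRAD or REST.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"samples without a group label: {missing[:5]}")
        bad = set(self.labels.unique()) - {PRAD, REST}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicated probe ids: {list(dups[:5])}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass(frozen=True)
class DmcRecord:
    """One differentially methylated CpG passing the threshold rule."""

    probe_id: str
    mean_prad: float
    mean_rest: float
    direction: str  # "hyper" or "hypo"
    island_id: str


@dataclass(frozen=True)
class CandidateIsland:
    """A CpG island with more than one unique member DMC."""

    island_id: str
    members: tuple[DmcRecord, ...]
    uniform_direction: bool
    direction: str | None          # hyper/hypo when uniform, else None
    separation: float              # min over members of |mean_prad - mean_rest|


@dataclass
class RfeConfig:
    """Recursive feature elimination settings.

    Scoring uses stratified k-fold cross-validation repeated ``n_repeats``
    times; each elimination round drops the lowest-importance
    ``elimination_fraction`` of the surviving features (at least one).  The
    returned subset is the smallest retained-set size whose mean CV accuracy
    is within one standard error of the best.
    """

    n_folds: int = 10
    n_repeats: int = 5
    elimination_fraction: float = 0.5
    ranker: str | Callable = "trees"   # "trees", "mean_diff", or callable
    seed: int = 0
    n_estimators: int = 25             # size of the CV scoring forest

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.elimination_fraction < 1:
            raise ValueError("elimination_fraction must be in (0, 1)")


@dataclass(frozen=True)
class RfeResult:
    ranking: tuple[str, ...]           # all probes, best first
    chosen: tuple[str, ...]            # one-standard-error subset
    path: pd.DataFrame                 # columns: n_features, mean_accuracy, se


def filter_complete_probes(matrix: BetaMatrix) -> BetaMatrix:
    """Keep exactly the probes with zero missing values."""
    if matrix.values.empty:
        raise ValueError("empty beta matrix")
    complete = matrix.values.dropna(axis=0, how="any")
    if complete.empty:
        raise ValueError("no probe with complete observations survives filtering")
    return BetaMatrix(complete, matrix.labels)


def group_mean_betas(matrix: BetaMatrix) -> pd.DataFrame:
    """Arithmetic mean beta per probe for the PRAD and REST groups.

    Expects a complete (post-filter) matrix; raises if a group has no
    samples.
    """
    for group in (PRAD, REST):
        if not (matrix.labels == group).any():
            raise ValueError(f"group {group} has no samples")
    if matrix.values.isna().any().any():
        raise ValueError("matrix contains missing values; filter probes first")
    prad_cols = matrix.sample_ids[matrix.labels == PRAD]
    rest_cols = matrix.sample_ids[matrix.labels == REST]
    return pd.DataFrame(
        {
            "mean_prad": matrix.values[prad_cols].mean(axis=1),
            "mean_rest": matrix.values[rest_cols].mean(axis=1),
        }
    )


def select_dmcs(
    means: pd.DataFrame,
    annotation: pd.DataFrame,
    hyper_hi: float = HYPER_HI_DEFAULT,
    lo: float = LO_DEFAULT,
) -> list[DmcRecord]:
    """Apply the strict-threshold DMC rule and the CpG-island restriction.

    ``annotation`` is indexed by probe_id with an ``island_id`` column
    (NaN/None for probes outside islands).  Probes not in the annotation or
    without an island are discarded even if they pass the thresholds.
    """
    if not lo < hyper_hi:
        raise ValueError("thresholds must satisfy lo < hyper_hi")
    records: list[DmcRecord] = []
    island_of = annotation["island_id"] if "island_id" in annotation else pd.Series(dtype=object)
    for probe_id, row in means.iterrows():
        mp, mr = float(row["mean_prad"]), float(row["mean_rest"])
        if mp > hyper_hi and mr < lo:
            direction = "hyper"
        elif mp < lo and mr > hyper_hi:
            direction = "hypo"
        else:
            continue
        island = island_of.get(probe_id)
        if island is None or (isinstance(island, float) and np.isnan(island)):
            continue
        records.append(DmcRecord(str(probe_id), mp, mr, direction, str(island)))
    return records


def _rank_features(X: np.ndarray, y: np.ndarray, ranker, seed: int) -> np.ndarray:
    """Per-feature importance, higher = more informative."""
    if callable(ranker):
        return np.asarray(ranker(X, y), dtype=float)
    if ranker == "mean_diff":
        # deterministic fallback: |mean beta difference| between groups
        g1 = X[y == 1].mean(axis=0)
        g0 = X[y == 0].mean(axis=0)
        return np.abs(g1 - g0)
    if ranker == "trees":
        clf = ExtraTreesClassifier(n_estimators=50, random_state=seed)
        clf.fit(X, y)
        return clf.feature_importances_
    raise ValueError(f"unknown ranker {ranker!r}")


def rfe_select(
    matrix: BetaMatrix,
    config: RfeConfig | None = None,
) -> RfeResult:
    """Recursive feature elimination over the DMC-restricted matrix.

    Features (probes) are repeatedly scored with the configured importance
    ranker and the weakest fraction dropped; each retained set's mean
    accuracy is estimated with repeated stratified k-fold cross-validation
    of a random-forest classifier.  Elimination order defines the ranking
    (survivors rank best); the chosen subset applies the one-standard-error
    rule to the accuracy path.
    """
    config = config or RfeConfig()
    if matrix.values.shape[0] < 1:
        raise ValueError("need at least one feature")
    X_full = matrix.values.to_numpy(dtype=float).T  # samples x features
    y = (matrix.labels.to_numpy() == PRAD).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    class_min = min(int((y == 1).sum()), int((y == 0).sum()))
    if class_min < config.n_folds:
        raise ValueError(
            f"stratified {config.n_folds}-fold CV needs >= {config.n_folds} "
            f"samples per class (smallest class has {class_min})"
        )

    feature_ids = list(matrix.probe_ids)
    active = list(range(len(feature_ids)))
    eliminated: list[int] = []          # in elimination order (worst first)
    path_rows = []
    rng_seed = config.seed

    cv = RepeatedStratifiedKFold(
        n_splits=config.n_folds, n_repeats=config.n_repeats, random_state=rng_seed
    )
    splits = list(cv.split(X_full, y))

    while active:
        X = X_full[:, active]
        scores = []
        for train, test in splits:
            clf = RandomForestClassifier(
                n_estimators=config.n_estimators, random_state=rng_seed
            )
            clf.fit(X[train], y[train])
            scores.append(float(clf.score(X[test], y[test])))
        scores_arr = np.asarray(scores)
        path_rows.append(
            {
                "n_features": len(active),
                "mean_accuracy": float(scores_arr.mean()),
                "se": float(scores_arr.std(ddof=1) / np.sqrt(len(scores_arr))),
            }
        )
        if len(active) == 1:
            eliminated.append(active.pop())
            break
        importance = _rank_features(X, y, config.ranker, rng_seed)
        n_drop = max(1, int(len(active) * config.elimination_fraction))
        n_drop = min(n_drop, len(active) - 1)
        # ties broken by position for determinism
        order = np.argsort(importance, kind="stable")
        drop_local = [int(j) for j in order[:n_drop]]  # worst first
        for j in drop_local:
            eliminated.append(active[j])
        for j in sorted(drop_local, reverse=True):
            del active[j]

    ranking_idx = list(reversed(eliminated))  # survivors first
    ranking = tuple(feature_ids[i] for i in ranking_idx)
    path = pd.DataFrame(path_rows)
    best = path["mean_accuracy"].max()
    se_best = float(path.loc[path["mean_accuracy"].idxmax(), "se"])
    ok = path[path["mean_accuracy"] >= best - se_best]
    chosen_size = int(ok["n_features"].min())
    chosen = ranking[:chosen_size]
    return RfeResult(ranking, chosen, path)


def select_candidate_islands(
    dmcs: Sequence[DmcRecord],
    annotation: pd.DataFrame | None = None,
) -> list[CandidateIsland]:
    """Keep CpG islands containing more than one unique member DMC.

    Manual inspection of per-group beta distributions is replaced by two
    auditable quantities per island: a uniform-direction flag and a
    separation score (min over members of |mean PRAD - mean REST|).
    """
    if not dmcs:
        raise ValueError("no DMC records supplied")
    by_island: dict[str, dict[str, DmcRecord]] = {}
    for rec in dmcs:
        by_island.setdefault(rec.island_id, {})[rec.probe_id] = rec
    islands = []
    for island_id, members in sorted(by_island.items()):
        if len(members) <= 1:
            continue
        recs = tuple(members[p] for p in sorted(members))
        dirs = {r.direction for r in recs}
        uniform = len(dirs) == 1
        islands.append(
            CandidateIsland(
                island_id=island_id,
                members=recs,
                uniform_direction=uniform,
                direction=next(iter(dirs)) if uniform else None,
                separation=min(abs(r.mean_prad - r.mean_rest) for r in recs),
            )
        )
    return islands


def discover_candidates(
    matrix: BetaMatrix,
    annotation: pd.DataFrame,
    hyper_hi: float = HYPER_HI_DEFAULT,
    lo: float = LO_DEFAULT,
    rfe_config: RfeConfig | None = None,
    run_rfe: bool = True,
) -> tuple[list[CandidateIsland], pd.DataFrame]:
    """Run the full discovery cascade; returns islands and a candidate table.

    The candidate table has one row per member DMC of each returned island:
    island_id, probe_id, mean_prad, mean_rest, direction, rfe_rank.
    """
    filtered = filter_complete_probes(matrix)
    means = group_mean_betas(filtered)
    dmcs = select_dmcs(means, annotation, hyper_hi=hyper_hi, lo=lo)
    if not dmcs:
        return [], pd.DataFrame(
            columns=["island_id", "probe_id", "mean_prad", "mean_rest",
                     "direction", "rfe_rank"]
        )
    rank_of: dict[str, int] = {}
    if run_rfe and len(dmcs) >= 2:
        dmc_ids = [r.probe_id for r in dmcs]
        sub = BetaMatrix(filtered.values.loc[dmc_ids], filtered.labels)
        try:
            rfe = rfe_select(sub, rfe_config)
            rank_of = {p: i + 1 for i, p in enumerate(rfe.ranking)}
        except ValueError as exc:  # e.g. too few samples per class for folds
            warnings.warn(f"RFE skipped: {exc}")
    islands = select_candidate_islands(dmcs)
    rows = [
        {
            "island_id": isl.island_id,
            "probe_id": rec.probe_id,
            "mean_prad": rec.mean_prad,
            "mean_rest": rec.mean_rest,
            "direction": rec.direction,
            "rfe_rank": rank_of.get(rec.probe_id, pd.NA),
        }
        for isl in islands
        for rec in isl.members
    ]
    return islands, pd.DataFrame(rows)
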