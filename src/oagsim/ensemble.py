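"""Exhaustive-subset neural-network ensemble for variable-importance ranking.

The procedure trains one small feed-forward network per non-empty subset of a
panel of candidate predictors (2^k − 1 subsets; 16 383 for the full 7-SNP +
7-clinical panel), each repeated R times (20 in the full analysis).  Every
run draws a fresh balanced cohort — all incident cases plus an equal number
of controls, sampled at random or greedily age-matched to within a tolerance
— splits it 70/15/15 into train/validation/test strata, trains with early
stopping on the validation split, and records the test-set error score (the
proportion of subjects misclassified at a 0.5 probability threshold).

A variable's *contribution* is the mean reduction in error score conferred
by adding it: error scores are averaged over reps per subset, and the paired
differences error(S) − error(S ∪ {v}) are averaged over every subset S that
omits v (2^(k−1) − 1 pairs).  A marginal difference-of-means estimator is
available as an alternative.  Variables are ranked by contribution,
descending, ties broken by panel order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

MAX_PANEL = 20  # enumeration guard: 2^20 subsets is already a million


class MatchingError(ValueError):
    """Age matching infeasible within the tolerance."""


@dataclass(frozen=True)
class VariablePanel:
    """Ordered candidate predictors: clinical variables and SNP dosages."""

    clinical: tuple[str, ...]
    snps: tuple[str, ...] = ()

    def __post_init__(self):
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("panel variable names must be unique")
        if not 1 <= len(names) <= MAX_PANEL:
            raise ValueError(f"panel size {len(names)} outside 1..{MAX_PANEL}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.clinical) + tuple(self.snps)

    @property
    def k(self) -> int:
        return len(self.names)

    def subset_names(self, mask: int) -> list[str]:
        return [v for i, v in enumerate(self.names) if mask >> i & 1]


def enumerate_subsets(panel: VariablePanel) -> np.ndarray:
    """All non-empty subsets of the panel as ascending bitmasks (1..2^k−1)."""
    return np.arange(1, 1 << panel.k, dtype=np.int64)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_balanced_cohort(cases: pd.DataFrame, controls: pd.DataFrame,
                           age_matched: bool = False,
                           tolerance_years: float = 2.0,
                           seed=None) -> pd.DataFrame:
    """All cases plus an equal number of controls, sampled without replacement.

    Unmatched mode takes a simple random sample of controls.  Matched mode
    visits cases in a seed-randomized order and greedily assigns each the
    unused control nearest in age (ties toward the younger control),
    requiring |case age − control age| <= ``tolerance_years``.
    """
    if len(controls) < len(cases):
        raise ValueError("need at least as many controls as cases")
    rng = _as_rng(seed)
    if not age_matched:
        idx = rng.choice(len(controls), size=len(cases), replace=False)
        picked = controls.iloc[idx]
    else:
        ctrl_age = controls["age"].to_numpy(dtype=float)
        order = np.argsort(ctrl_age, kind="stable")
        sorted_age = ctrl_age[order]
        used = np.zeros(len(controls), dtype=bool)
        case_order = rng.permutation(len(cases))
        chosen, unmatched = [], []
        for ci in case_order:
            age = float(cases["age"].iloc[ci])
            pos = np.searchsorted(sorted_age, age)
            best, best_diff = -1, np.inf
            # scan outward from the insertion point over unused controls
            lo, hi = pos - 1, pos
            while lo >= 0 or hi < len(sorted_age):
                lo_diff = age - sorted_age[lo] if lo >= 0 else np.inf
                hi_diff = sorted_age[hi] - age if hi < len(sorted_age) else np.inf
                if min(lo_diff, hi_diff) > min(best_diff, tolerance_years):
                    break
                if lo_diff <= hi_diff:  # tie -> younger control
                    j, diff = lo, lo_diff
                    lo -= 1
                else:
                    j, diff = hi, hi_diff
                    hi += 1
                if used[order[j]] or diff > tolerance_years:
                    continue
                if diff < best_diff:
                    best, best_diff = order[j], diff
            if best < 0:
                unmatched.append(age)
            else:
                used[best] = True
                chosen.append(best)
        if unmatched:
            raise MatchingError(
                f"no control within {tolerance_years} years for case ages "
                f"{sorted(round(a, 1) for a in unmatched)}")
        picked = controls.iloc[chosen]
    out = pd.concat([cases, picked], ignore_index=True)
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


def _part_sizes(n: int, fractions) -> list[int]:
    """Floor each fraction, hand remaining rows out train-first."""
    sizes = [int(np.floor(f * n)) for f in fractions]
    rem = n - sum(sizes)
    for i in range(rem):
        sizes[i % len(sizes)] += 1
    return sizes


def split_train_val_test(rows: pd.DataFrame,
                         fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                         seed=None) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Random status-stratified partition into train/validation/test.

    Sizes follow the floor-then-distribute-remainder-train-first rule applied
    within each status class, so every part contains both classes.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = _as_rng(seed)
    parts: list[list[pd.DataFrame]] = [[], [], []]
    for _, grp in rows.groupby("status", sort=True):
        idx = rng.permutation(len(grp))
        sizes = _part_sizes(len(grp), fractions)
        start = 0
        for p, size in enumerate(sizes):
            parts[p].append(grp.iloc[idx[start:start + size]])
            start += size
    out = [pd.concat(p, ignore_index=True) for p in parts]
    for name, part in zip(("train", "validation", "test"), out):
        if len(part) == 0:
            raise ValueError(f"{name} part is empty")
        if part["status"].nunique() < 2:
            raise ValueError(f"{name} part is single-class")
    return out[0], out[1], out[2]


class EarlyStoppingNet:
    """One-hidden-layer logistic feed-forward classifier, trained full-batch.

    Weights are fitted by gradient descent with momentum on the logistic
    cross-entropy, monitored on a caller-supplied validation set: training
    stops when validation error has not improved for ``patience``
    evaluations, and the best-scoring weights are restored.  Continuous
    inputs are standardized with training-set statistics; columns that are
    already small counts (sex 0/1, genotype dosages 0/1/2) enter unscaled.
    Everything is deterministic given the seed.
    """

    def __init__(self, n_hidden: int = 5, learning_rate: float = 0.5,
                 momentum: float = 0.9, max_epochs: int = 200,
                 patience: int = 10, seed=0):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))

    def _standardize(self, X):
        return (X - self._mu) / self._sd

    def fit(self, X_train: np.ndarray, y_train: np.ndarray,
            X_val: np.ndarray, y_val: np.ndarray) -> "EarlyStoppingNet":
        rng = _as_rng(self.seed)
        X = np.asarray(X_train, dtype=float)
        y = np.asarray(y_train, dtype=float)
        # leave 0/1/2-coded columns (sex, dosage) on their natural scale
        counts = np.all((X == np.round(X)) & (X >= 0) & (X <= 2), axis=0)
        self._mu = np.where(counts, 0.0, X.mean(axis=0))
        sd = X.std(axis=0)
        self._sd = np.where(counts | (sd == 0), 1.0, sd)
        Xs = self._standardize(X)
        Xv = self._standardize(np.asarray(X_val, dtype=float))
        yv = np.asarray(y_val, dtype=float)
        n, d = Xs.shape
        h = self.n_hidden
        scale = 1.0 / np.sqrt(d + 1)
        W1 = rng.normal(0.0, scale, size=(d, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(h + 1), size=h)
        b2 = 0.0
        vel = [np.zeros_like(W1), np.zeros_like(b1), np.zeros_like(W2), 0.0]
        best = (np.inf, W1.copy(), b1.copy(), W2.copy(), b2)
        bad = 0
        lr, mom = self.learning_rate, self.momentum
        for _ in range(self.max_epochs):
            H = self._sigmoid(Xs @ W1 + b1)
            p = self._sigmoid(H @ W2 + b2)
            delta = (p - y) / n                      # d(loss)/d(logit)
            gW2 = H.T @ delta
            gb2 = delta.sum()
            dH = np.outer(delta, W2) * H * (1.0 - H)
            gW1 = Xs.T @ dH
            gb1 = dH.sum(axis=0)
            for i, g in enumerate((gW1, gb1, gW2, gb2)):
                vel[i] = mom * vel[i] - lr * g
            W1 = W1 + vel[0]; b1 = b1 + vel[1]; W2 = W2 + vel[2]; b2 = b2 + vel[3]
            Hv = self._sigmoid(Xv @ W1 + b1)
            val_err = float(np.mean((self._sigmoid(Hv @ W2 + b2) >= 0.5) != (yv >= 0.5)))
            if val_err < best[0] - 1e-12:
                best = (val_err, W1.copy(), b1.copy(), W2.copy(), b2)
                bad = 0
            else:
                bad += 1
                if bad > self.patience:
                    break
        self.best_val_error_, self._W1, self._b1, self._W2, self._b2 = best
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = self._standardize(np.asarray(X, dtype=float))
        H = self._sigmoid(Xs @ self._W1 + self._b1)
        return self._sigmoid(H @ self._W2 + self._b2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int64)


def train_classifier(train: pd.DataFrame, validation: pd.DataFrame,
                     input_variables: list[str], seed,
                     **net_kwargs) -> EarlyStoppingNet:
    """Train the early-stopping network on the named input variables."""
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if train["status"].nunique() < 2:
        raise ValueError("training set must contain both classes")
    net = EarlyStoppingNet(seed=seed, **net_kwargs)
    net.input_variables_ = list(input_variables)
    net.fit(train[input_variables].to_numpy(dtype=float),
            train["status"].to_numpy(dtype=float),
            validation[input_variables].to_numpy(dtype=float),
            validation["status"].to_numpy(dtype=float))
    return net


def error_score(model: EarlyStoppingNet, test: pd.DataFrame) -> float:
    """Proportion of test subjects misclassified at threshold 0.5."""
    if len(test) == 0:
        raise ValueError("test set must be non-empty")
    pred = model.predict(test[model.input_variables_].to_numpy(dtype=float))
    return float(np.mean(pred != test["status"].to_numpy()))


def _run_seed(master_seed: int, mask: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed),
                                  spawn_key=(int(mask), int(rep)))


def run_ensemble(cases: pd.DataFrame, controls: pd.DataFrame,
                 panel: VariablePanel, reps: int = 20,
                 age_matched: bool = False, tolerance_years: float = 2.0,
                 master_seed: int = 0, subset_cap: int | None = None,
                 checkpoint: str | None = None,
                 progress_every: int | None = None,
                 net_kwargs: dict | None = None) -> pd.DataFrame:
    """Train and score one network per (subset, repetition).

    Returns a tidy frame with columns subset (bitmask), rep, error.  Per-run
    seeds derive deterministically from (master_seed, subset, rep), so any
    run can be reproduced in isolation.  ``subset_cap`` truncates the subset
    list (reduced mode for testing); ``checkpoint`` names an append-only TSV
    used to resume an interrupted sweep.
    """
    masks = enumerate_subsets(panel)
    if subset_cap is not None:
        masks = masks[:subset_cap]
    done: set[tuple[int, int]] = set()
    records: list[dict] = []
    existed = bool(checkpoint) and os.path.exists(checkpoint)
    if existed:
        prev = pd.read_csv(checkpoint, sep="\t")
        records = prev.to_dict("records")
        done = {(int(r["subset"]), int(r["rep"])) for r in records}
    ck = open(checkpoint, "a") if checkpoint else None
    if ck and not existed:
        ck.write("subset\trep\terror\n")
    kw = net_kwargs or {}
    try:
        n_done = 0
        for mask in masks:
            variables = panel.subset_names(int(mask))
            for rep in range(1, reps + 1):
                if (int(mask), rep) in done:
                    continue
                rng = np.random.default_rng(_run_seed(master_seed, int(mask), rep))
                cohort = sample_balanced_cohort(cases, controls, age_matched,
                                                tolerance_years, rng)
                train, val, test = split_train_val_test(cohort, seed=rng)
                net = train_classifier(train, val, variables, seed=rng, **kw)
                err = error_score(net, test)
                records.append({"subset": int(mask), "rep": rep, "error": err})
                if ck:
                    ck.write(f"{int(mask)}\t{rep}\t{err:.10g}\n")
                n_done += 1
                if progress_every and n_done % progress_every == 0:
                    print(f"[ensemble] {n_done} runs completed", flush=True)
    finally:
        if ck:
            ck.close()
    return pd.DataFrame.from_records(records, columns=["subset", "rep", "error"])


def variable_contribution(runs: pd.DataFrame, panel: VariablePanel,
                          variable: str, estimator: str = "paired") -> float:
    """Mean reduction in error score conferred by ``variable``.

    ``paired``: rep-averaged error scores are differenced over every pair
    (S, S ∪ {v}) with S non-empty, then averaged.  ``marginal``: difference
    of mean error between all subsets excluding and including v.
    """
    if variable not in panel.names:
        raise ValueError(f"{variable!r} not in panel")
    bit = 1 << panel.names.index(variable)
    mean_err = runs.groupby("subset")["error"].mean()
    masks = mean_err.index.to_numpy()
    has_v = (masks & bit) > 0
    if estimator == "marginal":
        return float(mean_err[~has_v].mean() - mean_err[has_v].mean())
    if estimator != "paired":
        raise ValueError(f"unknown estimator {estimator!r}")
    err = dict(zip(masks.tolist(), mean_err.to_numpy()))
    diffs = [err[m] - err[m | bit]
             for m in masks[~has_v] if (m | bit) in err]
    if not diffs:
        raise ValueError(f"no (S, S ∪ {{{variable}}}) pairs available in runs")
    return float(np.mean(diffs))


def rank_variables(runs: pd.DataFrame, panel: VariablePanel,
                   age_matched: bool = False,
                   estimator: str = "paired") -> pd.DataFrame:
    """Importance table: rank, variable, contribution (descending).

    Ties in contribution are broken by panel order (a stable sort over the
    panel-ordered variables).  In subset-capped (reduced) runs a variable
    may have no usable (S, S ∪ {v}) pair; it gets a NaN contribution and
    sorts last.
    """
    contrib = {}
    for v in panel.names:
        try:
            contrib[v] = variable_contribution(runs, panel, v, estimator)
        except ValueError:
            contrib[v] = np.nan
    table = pd.DataFrame({"variable": list(panel.names),
                          "contribution": [contrib[v] for v in panel.names]})
    table = table.sort_values("contribution", ascending=False,
                              kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    table["age_matched"] = bool(age_matched)
    return table


class SubsetEnsembleImportance(BaseEstimator):
    """sklearn-style wrapper: exhaustive-subset ensemble variable importance.

    ``fit(X, y)`` runs the full procedure on a feature frame ``X`` (columns
    are the panel) and binary outcome ``y``; fitted attributes expose the
    per-run error scores (``runs_``), per-variable contributions
    (``contributions_``, panel order) and the ranked importance table
    (``importances_``).
    """

    def __init__(self, reps: int = 3, age_matched: bool = False,
                 tolerance_years: float = 2.0, estimator: str = "paired",
                 subset_cap: int | None = None, random_state: int = 0):
        self.reps = reps
        self.age_matched = age_matched
        self.tolerance_years = tolerance_years
        self.estimator = estimator
        self.subset_cap = subset_cap
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "SubsetEnsembleImportance":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary 0/1")
        if self.age_matched and "age" not in X.columns:
            raise ValueError("age matching requires an 'age' column in X")
        panel = VariablePanel(clinical=tuple(map(str, X.columns)))
        frame = X.copy()
        frame.columns = panel.names
        frame["status"] = y
        self.panel_ = panel
        self.runs_ = run_ensemble(frame[frame["status"] == 1],
                                  frame[frame["status"] == 0], panel,
                                  reps=self.reps, age_matched=self.age_matched,
                                  tolerance_years=self.tolerance_years,
                                  master_seed=self.random_state,
                                  subset_cap=self.subset_cap)
        self.importances_ = rank_variables(self.runs_, panel,
                                           self.age_matched, self.estimator)
        order = {v: c for v, c in
                 zip(self.importances_["variable"], self.importances_["contribution"])}
        self.contributions_ = np.array([order[v] for v in panel.names])
        self.ranking_ = np.array(
            [int(self.importances_.loc[self.importances_["variable"] == v, "rank"].iloc[0])
             for v in panel.names])
        return self
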