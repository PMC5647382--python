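"""Minimal-signature design.

Triages genome-scale CpG loci down to a small, multiply-redundant signature:

1. moderated-t candidate selection — per-subgroup one-vs-rest contrasts with
   empirical-Bayes variance shrinkage, top 50 loci per subgroup pooled;
2. classifier-fusion ranking — four base learners (linear SVM, small neural
   network, decision tree, discretized naive Bayes) trained under stratified
   10-fold cross-validation in a two-stage class scheme, per-learner
   importances converted to ranks and averaged;
3. redundancy optimization — candidate signatures scored by cross-validated
   accuracy under random deletion of up to 6 member loci, with weak members
   swapped for next-ranked alternatives until the masked accuracy stops
   improving.

The design target is a signature that still classifies correctly when
several member loci fail in a degraded sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .matrix import BetaMatrix

__all__ = [
    "SignatureLocus",
    "SignatureDefinition",
    "CandidateSet",
    "FusionRanking",
    "moderated_t_stats",
    "fit_variance_prior",
    "select_candidates",
    "fusion_rank",
    "redundancy_optimize",
]


# ---------------------------------------------------------------------------
# Signature containers


@dataclass(frozen=True)
class SignatureLocus:
    locus_id: str
    contrast: str | None = None
    plex: int = 1
    chrom: str | None = None
    pos: int | None = None


@dataclass
class SignatureDefinition:
    """Ordered set of signature CpG loci with per-locus metadata."""

    loci: list[SignatureLocus]

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("signature loci must be unique")
        for l in self.loci:
            if l.plex not in (1, 2, 3):
                raise ValueError(f"plex must be 1, 2 or 3 (locus {l.locus_id})")

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @classmethod
    def from_ids(
        cls,
        ids: Sequence[str],
        contrasts: dict[str, str] | None = None,
    ) -> "SignatureDefinition":
        """Build a signature from locus ids, assigning multiplexes round-robin."""
        loci = [
            SignatureLocus(
                locus_id=l,
                contrast=(contrasts or {}).get(l),
                plex=(i % 3) + 1,
            )
            for i, l in enumerate(ids)
        ]
        return cls(loci=loci)


# ---------------------------------------------------------------------------
# Moderated t statistics (empirical-Bayes variance shrinkage)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-inverse-χ² prior to per-locus sample variances.

    Under the hierarchical model the sample variances are distributed as
    s² ~ s₀²·F(d, d₀).  Matching the mean and variance of the observed s²
    across loci to that F distribution gives

        d₀ = (4·r·d + 2·d − 4) / (r·d − 2),   r = Var(s²)/E[s²]²,
        s₀² = E[s²]·(d₀ − 2)/d₀,

    with d₀ = ∞ (complete shrinkage, s₀² = E[s²]) when the observed spread
    is no larger than sampling noise alone (r·d ≤ 2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    m1 = float(s2.mean())
    if m1 <= 0:
        raise ValueError("all sample variances are zero: degenerate prior fit")
    v = float(s2.var(ddof=1)) if s2.size > 1 else 0.0
    r = v / (m1 * m1)
    if r * df <= 2.0:
        return np.inf, m1
    d0 = (4.0 * r * df + 2.0 * df - 4.0) / (r * df - 2.0)
    if d0 <= 4.0:
        # Moment matching is unreliable at very heavy tails; fall back to a
        # weak prior rather than returning a non-finite variance.
        d0 = 4.0 + 1e-6
    s0 = m1 * (d0 - 2.0) / d0
    return float(d0), float(s0)


def moderated_t_stats(
    beta: BetaMatrix,
    labels: pd.Series | Sequence[str],
    subgroup: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """One-vs-rest moderated t statistics for every locus.

    Per locus: pooled two-sample variance s² with d = n₁+n₂−2 degrees of
    freedom, shrunk toward the moment-matched prior (d₀, s₀²),

        s̃² = (d₀·s₀² + d·s²) / (d₀ + d),
        t̃  = Δβ / (s̃·√(1/n₁ + 1/n₂)),

    two-sided p-values from the t distribution with d + d₀ degrees of
    freedom, Benjamini–Hochberg adjusted.  ``prior_df`` overrides the fitted
    d₀ (0 recovers the ordinary t, ∞ full shrinkage to s₀²).

    Missing β entries are handled pairwise-complete with per-locus n.
    """
    y = pd.Series(list(labels), index=beta.sample_ids)
    in_mask = (y == subgroup).to_numpy()
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError(f"need >=2 samples in and out of subgroup {subgroup!r}")
    X = beta.to_numpy()
    present = ~np.isnan(X)

    def _group_stats(mask):
        P = present[mask]
        n = P.sum(axis=0)
        vals = np.where(P, X[mask], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = vals.sum(axis=0) / n
            ss = ((np.where(P, X[mask] - mean, 0.0)) ** 2).sum(axis=0)
            var = ss / np.maximum(n - 1, 1)
        return n, mean, var

    n1, mean1, var1 = _group_stats(in_mask)
    n2, mean2, var2 = _group_stats(~in_mask)
    if (n1 < 2).any() or (n2 < 2).any():
        bad = beta.locus_ids[int(np.argmax((n1 < 2) | (n2 < 2)))]
        raise ValueError(f"locus {bad!r} has <2 complete observations in a group")

    diff = mean1 - mean2
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / df_resid
    d_typ = float(np.median(df_resid))

    if prior_df is None:
        d0, s0 = fit_variance_prior(s2, d_typ)
    elif prior_df == 0:
        d0, s0 = 0.0, float(np.mean(s2))
    elif np.isinf(prior_df):
        _, s0 = fit_variance_prior(s2, d_typ)
        d0 = np.inf
    else:
        d0 = float(prior_df)
        _, s0 = fit_variance_prior(s2, d_typ)

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_mod = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        t_mod = np.where(se > 0, diff / se, 0.0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")

    return pd.DataFrame(
        {
            "locus_id": beta.locus_ids,
            "subgroup": subgroup,
            "n_in": n1,
            "n_out": n2,
            "mean_difference": diff,
            "ordinary_s2": s2,
            "moderated_s2": s2_mod,
            "prior_df": d0,
            "prior_var": s0,
            "moderated_t": t_mod,
            "p_value": p,
            "adjusted_p": p_adj,
        }
    )


# ---------------------------------------------------------------------------
# Candidate selection


@dataclass
class CandidateSet:
    """Top differentially methylated loci per subgroup, pooled."""

    per_subgroup: dict[str, list[str]]
    pooled: list[str]
    rejected: pd.DataFrame  # columns: locus_id, subgroup, reason
    contrasts: dict[str, str] = field(default_factory=dict)


def select_candidates(
    stats_by_group: dict[str, pd.DataFrame],
    per_group_k: int = 50,
    design_filter: Callable[[str], tuple[bool, str]] | None = None,
) -> CandidateSet:
    """Top ``per_group_k`` loci by |moderated t| per subgroup, pooled.

    ``design_filter`` emulates the in-silico assay-design triage: it maps a
    locus id to ``(passed, reason)``; rejected loci are recorded and replaced
    by the next-ranked locus of the same contrast.  Default passes all.
    """
    per_subgroup: dict[str, list[str]] = {}
    rejected_rows = []
    contrasts: dict[str, str] = {}
    for group, table in stats_by_group.items():
        ranked = table.sort_values(
            by=["moderated_t", "locus_id"],
            key=lambda c: -c.abs() if c.name == "moderated_t" else c,
        )
        chosen: list[str] = []
        for locus in ranked["locus_id"]:
            if design_filter is not None:
                ok, reason = design_filter(locus)
                if not ok:
                    rejected_rows.append(
                        {"locus_id": locus, "subgroup": group, "reason": reason}
                    )
                    continue
            chosen.append(locus)
            if len(chosen) == per_group_k:
                break
        if len(chosen) < per_group_k:
            raise ValueError(
                f"subgroup {group!r}: only {len(chosen)} eligible loci, "
                f"need {per_group_k}"
            )
        per_subgroup[group] = chosen
        for locus in chosen:
            contrasts.setdefault(locus, group)
    pooled: list[str] = []
    seen: set[str] = set()
    for group in stats_by_group:
        for locus in per_subgroup[group]:
            if locus not in seen:
                seen.add(locus)
                pooled.append(locus)
    rejected = pd.DataFrame(rejected_rows, columns=["locus_id", "subgroup", "reason"])
    return CandidateSet(
        per_subgroup=per_subgroup, pooled=pooled, rejected=rejected, contrasts=contrasts
    )


# ---------------------------------------------------------------------------
# Classifier-fusion ranking


@dataclass
class FusionRanking:
    """Per-locus ranks under each base learner plus the fused rank."""

    table: pd.DataFrame  # index locus_id; rank_/importance_ columns, fused_rank
    scheme: str
    contrasts: dict[str, str] = field(default_factory=dict)

    def ordered_loci(self) -> list[str]:
        return list(self.table.sort_values("fused_rank").index)


def default_stages(labels: pd.Series) -> list[tuple[str, dict[str, str]]]:
    """Two-stage class scheme for the four consensus subgroups.

    Stage 1 is the three-class model (WNT vs SHH vs Grp3∪Grp4), stage 2 the
    two-class model (Grp3 vs Grp4).  Any other label set falls back to a
    single flat multi-class stage.
    """
    present = set(pd.Series(labels).unique())
    if present == {"WNT", "SHH", "Grp3", "Grp4"}:
        return [
            ("three_class", {"WNT": "WNT", "SHH": "SHH", "Grp3": "Grp3_4", "Grp4": "Grp3_4"}),
            ("two_class", {"Grp3": "Grp3", "Grp4": "Grp4"}),
        ]
    return [("flat", {g: g for g in sorted(present, key=str)})]


def _nb_bin(X: np.ndarray) -> np.ndarray:
    """Discretize β into unmethylated (<0.25) / hemi / methylated (>0.75)."""
    return np.digitize(X, [0.25, 0.75])


def _nb_importance(Xb: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Naive-Bayes locus score: mean pairwise L1 distance between the
    class-conditional bin distributions (Laplace-smoothed)."""
    classes = np.unique(y)
    n_loci = Xb.shape[1]
    probs = np.empty((len(classes), n_loci, 3))
    for ci, c in enumerate(classes):
        sub = Xb[y == c]
        for b in range(3):
            probs[ci, :, b] = ((sub == b).sum(axis=0) + 1.0) / (len(sub) + 3.0)
    score = np.zeros(n_loci)
    n_pairs = 0
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            score += np.abs(probs[i] - probs[j]).sum(axis=1)
            n_pairs += 1
    return score / max(n_pairs, 1)


def _permutation_importance(model, X_val, y_val, rng) -> np.ndarray:
    base = (model.predict(X_val) == y_val).mean()
    imp = np.zeros(X_val.shape[1])
    for j in range(X_val.shape[1]):
        saved = X_val[:, j].copy()
        X_val[:, j] = saved[rng.permutation(len(saved))]
        imp[j] = base - (model.predict(X_val) == y_val).mean()
        X_val[:, j] = saved
    return imp


def fusion_rank(
    beta: BetaMatrix,
    labels: pd.Series | Sequence[str],
    stages: list[tuple[str, dict[str, str]]] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    contrasts: dict[str, str] | None = None,
) -> FusionRanking:
    """Rank candidate loci by fused importance across four learner families.

    Within each stage of the class scheme, each learner is trained per
    stratified CV fold; per-locus importances are averaged across folds,
    converted to dense ranks (1 = most important), and the fused rank is the
    mean of the per-learner, per-stage ranks.  Ties are broken by mean
    absolute importance then locus id.
    """
    y_all = pd.Series(list(labels), index=beta.sample_ids)
    stages = stages if stages is not None else default_stages(y_all)
    loci = beta.locus_ids
    filled = beta.fill_median()
    rng = np.random.default_rng(seed)

    learner_names = ["svm", "ann", "dt", "nb"]
    importance: dict[str, np.ndarray] = {}

    for stage_name, mapping in stages:
        keep = y_all.isin(mapping.keys())
        y_stage = y_all[keep].map(mapping)
        X = filled.values.loc[keep.index[keep], loci].to_numpy()
        y = y_stage.to_numpy()
        min_class = pd.Series(y).value_counts().min()
        folds = min(n_folds, int(min_class))
        if folds < 2:
            raise ValueError(
                f"stage {stage_name!r}: smallest class too small for stratified CV"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        sums = {name: np.zeros(len(loci)) for name in learner_names}
        for train_idx, val_idx in skf.split(X, y):
            Xtr, ytr = X[train_idx], y[train_idx]
            Xva, yva = X[val_idx].copy(), y[val_idx]

            svm = LinearSVC(C=1.0, max_iter=5000).fit(Xtr, ytr)
            coef = np.atleast_2d(svm.coef_)
            sums["svm"] += np.abs(coef).mean(axis=0)

            ann = MLPClassifier(
                hidden_layer_sizes=(16,),
                solver="lbfgs",
                max_iter=300,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(Xtr, ytr)
            sums["ann"] += _permutation_importance(ann, Xva, yva, rng)

            dt = DecisionTreeClassifier(
                random_state=int(rng.integers(2**31 - 1))
            ).fit(Xtr, ytr)
            sums["dt"] += dt.feature_importances_

            sums["nb"] += _nb_importance(_nb_bin(Xtr), ytr)
        for name in learner_names:
            key = f"{stage_name}:{name}"
            importance[key] = sums[name] / folds

    table = pd.DataFrame(index=pd.Index(loci, name="locus_id"))
    rank_cols = []
    for key, imp in importance.items():
        table[f"importance_{key}"] = imp
        order = sorted(range(len(loci)), key=lambda i: (-imp[i], loci[i]))
        ranks = np.empty(len(loci))
        for r, i in enumerate(order, start=1):
            ranks[i] = r
        col = f"rank_{key}"
        table[col] = ranks
        rank_cols.append(col)
    table["mean_abs_importance"] = table[[c for c in table if c.startswith("importance_")]].abs().mean(axis=1)
    table["fused_rank"] = table[rank_cols].mean(axis=1)
    table = table.sort_values(
        by=["fused_rank", "mean_abs_importance", "locus_id"],
        ascending=[True, False, True],
    )
    scheme = f"{len(stages)}-stage, {n_folds}-fold stratified CV"
    return FusionRanking(table=table, scheme=scheme, contrasts=dict(contrasts or {}))


# ---------------------------------------------------------------------------
# Redundancy optimization


def _masked_cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    cols: np.ndarray,
    n_iter: int,
    max_remove: int,
    rng: np.random.Generator,
    n_folds: int = 10,
) -> float:
    """Mean stratified-CV accuracy over random deletions of up to
    ``max_remove`` of the given columns."""
    min_class = pd.Series(y).value_counts().min()
    folds = min(n_folds, int(min_class))
    accs = []
    for _ in range(n_iter):
        r = int(rng.integers(0, max_remove + 1))
        keep = cols if r == 0 else rng.choice(cols, size=len(cols) - r, replace=False)
        Xs = X[:, keep]
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        fold_acc = []
        for tr, va in skf.split(Xs, y):
            clf = LinearSVC(C=1.0, max_iter=5000).fit(Xs[tr], y[tr])
            fold_acc.append((clf.predict(Xs[va]) == y[va]).mean())
        accs.append(np.mean(fold_acc))
    return float(np.mean(accs))


def redundancy_optimize(
    ranking: FusionRanking,
    beta: BetaMatrix,
    labels: pd.Series | Sequence[str],
    target_size: int = 17,
    max_remove: int = 6,
    n_iter: int = 30,
    seed: int = 0,
    max_rounds: int = 8,
) -> SignatureDefinition:
    """Select the final signature by masked-accuracy greedy search.

    Starting from the ``target_size`` top-ranked loci, each round scores the
    current signature by cross-validated accuracy under random deletion of
    0–``max_remove`` loci, identifies the member whose removal degrades that
    masked accuracy least, and trials swapping it for the next-ranked
    alternative; the swap is kept only if the masked accuracy improves.
    ``n_iter`` masks are drawn per score; ``n_iter=0`` disables the search
    and returns the top-ranked loci unchanged.
    """
    ordered = ranking.ordered_loci()
    if len(ordered) < target_size:
        raise ValueError(
            f"need >= {target_size} candidates, have {len(ordered)}"
        )
    if n_iter > 0 and len(ordered) < target_size + 1:
        n_iter = 0  # nothing to swap in

    def _make(ids: Sequence[str]) -> SignatureDefinition:
        return SignatureDefinition.from_ids(list(ids), contrasts=ranking.contrasts)

    current = list(ordered[:target_size])
    if n_iter == 0:
        return _make(current)

    y = pd.Series(list(labels), index=beta.sample_ids).to_numpy()
    filled = beta.fill_median()
    X = filled.values.loc[:, ordered].to_numpy()
    col_of = {l: i for i, l in enumerate(ordered)}
    rng = np.random.default_rng(seed)

    def score(ids: list[str], r: np.random.Generator) -> float:
        return _masked_cv_accuracy(
            X, y, np.asarray([col_of[l] for l in ids]), n_iter, max_remove, r
        )

    next_idx = target_size
    best = score(current, np.random.default_rng(seed + 1))
    for _ in range(max_rounds):
        if next_idx >= len(ordered):
            break
        # Weakest member: the locus whose removal hurts masked accuracy least.
        drop_scores = {
            l: _masked_cv_accuracy(
                X,
                y,
                np.asarray([col_of[o] for o in current if o != l]),
                max(n_iter // 2, 5),
                max_remove,
                np.random.default_rng(seed + 100 + col_of[l]),
            )
            for l in current
        }
        weakest = max(drop_scores, key=lambda l: (drop_scores[l], l))
        candidate = [l for l in current if l != weakest] + [ordered[next_idx]]
        cand_score = score(candidate, np.random.default_rng(seed + 200 + next_idx))
        next_idx += 1
        if cand_score > best + 1e-9:
            current = candidate
            best = cand_score
        else:
            break  # masked accuracy has stabilized

    # Preserve fused-rank order in the emitted signature.
    current.sort(key=lambda l: col_of[l])
    return _make(current)
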