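"""Connectome similarity and its decomposition into sources of variance.

Whole-connectome similarity between two sessions is the product-moment
correlation of their upper-triangle edge vectors, Fisher-transformed to a
z score (``arctanh``, with |r| clipped at 1 - 1e-7 so identical
connectomes stay finite).  Session pairs are then grouped into four
categories — pairs from the same *individual*, pairs of different
subjects in the same *dataset*, pairs of different subjects with the
same *HC use* status, and all different-subject (*group*) pairs — and
mean z is compared between categories with Welch two-sample t tests at
α < 0.01.  Subtracting two category means gives the *normalized effect
magnitude* of one factor relative to another.

The four categories are overlapping by definition (every same-dataset
pair is also a group pair), so each pair carries one membership flag per
category plus a mutually exclusive ``primary`` label (individual >
dataset > hc_use > group) for plotting.  Category summaries use the
membership flags by default.  Note that pairwise z values sharing a
session are not independent observations; the t tests ignore this.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Study

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "CategorySimilarity",
    "pairwise_similarity",
    "classify_pairs",
    "category_summary",
    "normalized_effect_magnitude",
    "similarity_long_table",
]

_CLIP = 1.0 - 1e-7
CATEGORIES = ("individual", "dataset", "hc_use", "group")


@dataclass
class SimilarityMatrix:
    """Session-pair similarity: Pearson r and Fisher z, plus a validity mask."""

    session_ids: list[str]
    r: np.ndarray
    z: np.ndarray
    defined: np.ndarray  # False where an edge vector had zero variance

    @property
    def n_sessions(self) -> int:
        return len(self.session_ids)


@dataclass
class CategorySimilarity:
    """Per-category descriptives and pairwise Welch contrasts."""

    summary: pd.DataFrame  # category, n_pairs, mean_z, sd_z
    contrasts: pd.DataFrame  # category_a, category_b, t, df, p, significant
    alpha: float


def pairwise_similarity(study: Study) -> SimilarityMatrix:
    """Fisher-z similarity between every pair of session connectomes."""
    if study.n_sessions < 2:
        raise ValueError("need at least two sessions")
    E = study.edge_matrix()
    sd = E.std(axis=1)
    ok = sd > 0
    if not ok.all():
        logger.warning(
            "%d session(s) have zero-variance edge vectors; their pairs "
            "are flagged undefined", int((~ok).sum()),
        )
    S = study.n_sessions
    r = np.full((S, S), np.nan)
    if ok.any():
        sub = np.corrcoef(E[ok])
        r[np.ix_(ok, ok)] = sub
    defined = np.outer(ok, ok)
    np.fill_diagonal(r, 1.0)
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    ids = [
        f"{row.subject_id}_{row.session_id}" for row in study.sessions.itertuples()
    ]
    return SimilarityMatrix(session_ids=ids, r=r, z=z, defined=defined)


def classify_pairs(sessions: pd.DataFrame) -> pd.DataFrame:
    """Label every unordered session pair with its category memberships.

    Returns a long table with positional indices ``a`` and ``b``
    (``a < b``, matching the session-table row order), one boolean
    membership column per category, and a mutually exclusive ``primary``
    label with precedence individual > dataset > hc_use > group.  Pairs
    involving a session with a missing subject/dataset/HC label are
    marked ``excluded``.
    """
    subj = sessions["subject_id"].to_numpy()
    dset = sessions["dataset_id"].to_numpy()
    hc = sessions["hc_use"].to_numpy()
    valid = (
        pd.notna(sessions["subject_id"])
        & pd.notna(sessions["dataset_id"])
        & pd.notna(sessions["hc_use"])
    ).to_numpy()
    rows = []
    n_excluded = 0
    for a, b in itertools.combinations(range(len(sessions)), 2):
        if not (valid[a] and valid[b]):
            rows.append(
                {"a": a, "b": b, "individual": False, "dataset": False,
                 "hc_use": False, "group": False, "primary": "excluded"}
            )
            n_excluded += 1
            continue
        same_subj = subj[a] == subj[b]
        is_individual = bool(same_subj)
        is_dataset = bool(not same_subj and dset[a] == dset[b])
        is_hc = bool(not same_subj and hc[a] == hc[b])
        is_group = bool(not same_subj)
        if is_individual:
            primary = "individual"
        elif is_dataset:
            primary = "dataset"
        elif is_hc:
            primary = "hc_use"
        else:
            primary = "group"
        rows.append(
            {"a": a, "b": b, "individual": is_individual, "dataset": is_dataset,
             "hc_use": is_hc, "group": is_group, "primary": primary}
        )
    if n_excluded:
        logger.warning("%d pair(s) excluded for missing labels", n_excluded)
    return pd.DataFrame(rows)


def category_summary(
    sim: SimilarityMatrix,
    pairs: pd.DataFrame,
    alpha: float = 0.01,
    use: str = "membership",
) -> CategorySimilarity:
    """Mean/SD of Fisher z per category plus Welch contrasts.

    ``use='membership'`` evaluates each category over all pairs meeting
    its own definition (the default); ``use='primary'`` uses the
    mutually exclusive labels.  Categories with fewer than two defined
    pairs are reported descriptively and excluded from the t tests.
    """
    if use not in {"membership", "primary"}:
        raise ValueError("use must be 'membership' or 'primary'")
    a = pairs["a"].to_numpy()
    b = pairs["b"].to_numpy()
    zvals = sim.z[a, b]
    defined = sim.defined[a, b]
    groups: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        if use == "membership":
            member = pairs[cat].to_numpy()
        else:
            member = (pairs["primary"] == cat).to_numpy()
        groups[cat] = zvals[member & defined]
    summary = pd.DataFrame(
        {
            "category": list(groups),
            "n_pairs": [g.size for g in groups.values()],
            "mean_z": [g.mean() if g.size else np.nan for g in groups.values()],
            "sd_z": [g.std(ddof=1) if g.size > 1 else np.nan for g in groups.values()],
        }
    )
    rows = []
    testable = [c for c, g in groups.items() if g.size >= 2]
    for ca, cb in itertools.combinations(testable, 2):
        ga, gb = groups[ca], groups[cb]
        if np.ptp(ga) == 0 and np.ptp(gb) == 0 and ga[0] == gb[0]:
            # identical constant samples: no evidence of any difference
            t, df, p = 0.0, float(ga.size + gb.size - 2), 1.0
        else:
            res = stats.ttest_ind(ga, gb, equal_var=False)
            t, df, p = float(res.statistic), float(res.df), float(res.pvalue)
        rows.append(
            {"category_a": ca, "category_b": cb, "t": t, "df": df, "p": p,
             "significant": bool(p < alpha)}
        )
    contrasts = pd.DataFrame(
        rows, columns=["category_a", "category_b", "t", "df", "p", "significant"]
    )
    return CategorySimilarity(summary=summary, contrasts=contrasts, alpha=alpha)


def normalized_effect_magnitude(z_a: float, z_b: float) -> float:
    """Difference of mean Fisher-z similarities between two categories.

    Comparing, e.g., within-individual similarity against group-level
    similarity isolates the relative contribution of individual-specific
    factors after accounting for what all sessions share.
    """
    return float(z_a) - float(z_b)


def similarity_long_table(sim: SimilarityMatrix, pairs: pd.DataFrame) -> pd.DataFrame:
    """Long-format pair table (session ids, r, z, memberships, primary)."""
    a = pairs["a"].to_numpy()
    b = pairs["b"].to_numpy()
    out = pairs.copy()
    out.insert(0, "session_a", [sim.session_ids[i] for i in a])
    out.insert(1, "session_b", [sim.session_ids[j] for j in b])
    out["r"] = sim.r[a, b]
    out["z"] = sim.z[a, b]
    out["defined"] = sim.defined[a, b]
    return out
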