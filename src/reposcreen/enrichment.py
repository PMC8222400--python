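"""Gene-set enrichment screening of drug perturbation signatures.

Each drug profile is a single ranked signature: one real differential
statistic per gene.  The screen asks whether the disease gene set
concentrates at a rank extreme of the profile — interpreted, when the
extreme opposes the disease signature, as potential signature reversal.
The score is the classic weighted Kolmogorov–Smirnov-style running sum:
walking down the ranked list, the sum rises by |stat|^p / sum(|stat|^p)
at member genes and falls by 1/(N - N_hit) at non-members; the
enrichment score (ES) is the signed extremum of the walk, in [-1, 1].

Nominal p-values come from gene-label permutations (random member sets of
the same size, add-one estimator, two-sided on |ES| by default), and the
Benjamini–Hochberg step-up controls the FDR across all screened drugs.
A generic hypergeometric over-representation test against user-supplied
term annotations is provided for downstream functional profiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "EnrichmentResult",
    "rank_profile",
    "enrichment_score",
    "permutation_pvalue",
    "bh_fdr",
    "select_candidates",
    "hypergeometric_ora",
    "SignatureEnrichment",
    "SignatureEnrichmentResults",
]

_TIERS = (0.25, 0.1)


@dataclass
class EnrichmentResult:
    drug_id: str
    es: float
    p_nominal: float
    fdr: float
    n_perm: int
    tier: str


def rank_profile(profile: Mapping[str, float] | pd.Series) -> list[str]:
    """Genes sorted by statistic descending; ties broken by symbol ascending."""
    items = (
        profile.items() if isinstance(profile, Mapping) else profile.items()
    )
    return [g for g, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))]


def _walk_increments(
    stats: np.ndarray, member_mask: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """Per-position step sizes of the running sum (already signed)."""
    n = stats.size
    n_hit = int(member_mask.sum())
    if n_hit == 0:
        raise InvalidParameterError("gene set does not overlap the ranked list")
    w = np.abs(stats) ** weight_exponent
    norm = w[member_mask].sum()
    inc = np.zeros(n)
    if norm > 0:
        inc[member_mask] = w[member_mask] / norm
    else:  # all member stats are zero: fall back to equal steps
        inc[member_mask] = 1.0 / n_hit
    if n > n_hit:
        inc[~member_mask] = -1.0 / (n - n_hit)
    return inc


def _signed_extremum(running: np.ndarray) -> float:
    hi = float(running.max(initial=0.0))
    lo = float(running.min(initial=0.0))
    return hi if hi >= -lo else lo


def enrichment_score(
    ranked_genes: Sequence[str],
    stats: Sequence[float],
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> float:
    """ES of a gene set on a ranked list: signed extremum of the walk.

    ``ranked_genes`` must already be in rank order (descending statistic)
    with ``stats`` aligned; use :func:`rank_profile` to order a raw
    profile.  ES lies in [-1, 1]; when the set covers the whole list the
    walk only rises and ES = 1.
    """
    genes = list(ranked_genes)
    arr = np.asarray(stats, dtype=float)
    if arr.size != len(genes):
        raise InvalidParameterError("stats must align with ranked_genes")
    members = set(gene_set)
    mask = np.fromiter((g in members for g in genes), bool, count=len(genes))
    inc = _walk_increments(arr, mask, weight_exponent)
    running = np.cumsum(inc)
    return _signed_extremum(running)


def _es_from_positions(
    weights: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Vectorised ES for many member-position sets on one ranked list.

    ``positions`` is (n_draws, k) of 0-based ranks.  For sorted member
    positions p_1 < ... < p_k, the walk's value just after member i is
    cumhit_i / NR - (p_i + 1 - i) / (N - k), and just before member i it
    is cumhit_{i-1} / NR - (p_i - (i - 1)) / (N - k); the maxima of the
    former and minima of the latter bracket the walk's extrema because
    the sum only rises at members.
    """
    n = weights.size
    n_draws, k = positions.shape
    if k >= n:
        return np.ones(n_draws)
    pos = np.sort(positions, axis=1)
    w = weights[pos]
    cum = np.cumsum(w, axis=1)
    nr = cum[:, -1:]
    i = np.arange(1, k + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_hit = np.where(nr > 0, cum / nr, i / k)
    miss = 1.0 / (n - k)
    after = frac_hit - (pos + 1 - i) * miss
    before = np.concatenate(
        [np.zeros((n_draws, 1)), frac_hit[:, :-1]], axis=1
    ) - (pos - (i - 1)) * miss
    hi = np.maximum(after.max(axis=1), 0.0)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def permutation_pvalue(
    ranked_genes: Sequence[str],
    stats: Sequence[float],
    gene_set: Iterable[str],
    es_obs: float,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    alternative: str = "two-sided",
) -> float:
    """Gene-label permutation p-value for an observed ES.

    Null member sets of the same overlap size are drawn uniformly without
    replacement; the add-one estimator
    p = (1 + #{null at least as extreme}) / (1 + n_perm) keeps p in
    (0, 1].  ``alternative`` is ``two-sided`` on |ES| (default),
    ``greater`` or ``less``.
    """
    if n_perm < 100:
        raise InvalidParameterError(f"n_perm must be >= 100, got {n_perm}")
    genes = list(ranked_genes)
    n = len(genes)
    members = set(gene_set) & set(genes)
    k = len(members)
    if k == 0:
        raise InvalidParameterError("gene set does not overlap the ranked list")
    weights = np.abs(np.asarray(stats, dtype=float)) ** weight_exponent
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n))
    positions = np.argpartition(keys, k - 1, axis=1)[:, :k]
    es_null = _es_from_positions(weights, positions)
    if alternative == "two-sided":
        exceed = np.abs(es_null) >= abs(es_obs)
    elif alternative == "greater":
        exceed = es_null >= es_obs
    elif alternative == "less":
        exceed = es_null <= es_obs
    else:
        raise InvalidParameterError(f"unknown alternative {alternative!r}")
    return float((1 + exceed.sum()) / (1 + n_perm))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    q_i = min_{j >= i} p_(j) * m / j on the ascending-sorted p-values,
    clipped at 1.

    Raises
    ------
    ValidationError
        If any p lies outside [0, 1].
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tier_label(fdr: float, tiers: tuple[float, float] = _TIERS) -> str:
    loose, strict = max(tiers), min(tiers)
    if fdr < strict:
        return f"fdr_lt_{str(strict).replace('.', '_')}"
    if fdr < loose:
        return f"fdr_lt_{str(loose).replace('.', '_')}"
    return "not_significant"


def select_candidates(
    results: pd.DataFrame | Iterable[EnrichmentResult],
    tiers: tuple[float, float] = _TIERS,
) -> pd.DataFrame:
    """Tiered candidate table, sorted by FDR then |ES| descending.

    Tier membership is strict (FDR exactly at a cutoff is outside the
    tier).  Adds boolean ``pass_fdr_*`` columns for each cutoff and a
    ``tier`` label for the finest tier reached.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [
                {
                    "drug_id": r.drug_id,
                    "es": r.es,
                    "p_nominal": r.p_nominal,
                    "fdr": r.fdr,
                    "n_perm": r.n_perm,
                }
                for r in results
            ]
        )
    df = results.copy()
    if df.empty:
        for t in sorted(tiers, reverse=True):
            df[f"pass_fdr_{str(t).replace('.', '_')}"] = pd.Series(dtype=bool)
        df["tier"] = pd.Series(dtype=str)
        return df
    for t in sorted(tiers, reverse=True):
        df[f"pass_fdr_{str(t).replace('.', '_')}"] = df["fdr"] < t
    df["tier"] = [_tier_label(f, tiers) for f in df["fdr"]]
    df = df.sort_values(
        ["fdr", "es"], key=lambda s: s.abs() if s.name == "es" else s,
        ascending=[True, False],
    )
    return df.reset_index(drop=True)


def hypergeometric_ora(
    query_set: Iterable[str],
    term_annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    For each term with K genes in a universe of N, and a query of k
    genes overlapping the term in x, p = P(X >= x) under sampling
    without replacement.  BH adjusts across terms; ``significant``
    flags fdr < ``fdr_threshold``.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("universe must be non-empty")
    query = set(query_set)
    if not query <= uni:
        raise ValidationError("query set must be a subset of the universe")
    n_uni, n_query = len(uni), len(query)
    rows = []
    for term in term_annotation:
        term_genes = set(term_annotation[term])
        if not term_genes <= uni:
            raise ValidationError(f"term {term!r} has genes outside the universe")
        overlap = len(term_genes & query)
        p = float(hypergeom.sf(overlap - 1, n_uni, len(term_genes), n_query))
        rows.append(
            {
                "term": term,
                "overlap": overlap,
                "k": n_query,
                "K": len(term_genes),
                "N": n_uni,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["fdr"] < fdr_threshold
    return df.sort_values(["p", "term"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model / Results


class SignatureEnrichment:
    """Enrichment screen of drug perturbation profiles against a gene set.

    Parameters
    ----------
    profiles
        Genes x drugs DataFrame of differential statistics (one ranked
        signature per drug).
    gene_set
        Disease gene symbols to test for rank-extreme concentration.
    weight_exponent
        Exponent p on |stat| in the walk increments (default 1).
    alternative
        Sidedness of the permutation test; two-sided on |ES| by default
        so enrichment at either extreme can flag a candidate.
    """

    def __init__(
        self,
        profiles: pd.DataFrame,
        gene_set: Iterable[str],
        weight_exponent: float = 1.0,
        alternative: str = "two-sided",
    ):
        if profiles.shape[0] < 10:
            raise InvalidParameterError(
                "profiles must cover at least 10 genes"
            )
        if profiles.index.duplicated().any():
            raise InvalidParameterError("duplicate genes in profile matrix")
        self.profiles = profiles
        self.gene_set = set(gene_set)
        self.weight_exponent = weight_exponent
        self.alternative = alternative

    def fit(self, n_perm: int = 1000, seed: int = 0) -> "SignatureEnrichmentResults":
        """Score every profile; permutation p per drug, BH across drugs."""
        from .proximity import _derive_seed

        rows = []
        for drug in self.profiles.columns:
            profile = self.profiles[drug]
            ranked = rank_profile(profile)
            stats = profile.loc[ranked].to_numpy(dtype=float)
            es = enrichment_score(
                ranked, stats, self.gene_set, self.weight_exponent
            )
            p = permutation_pvalue(
                ranked,
                stats,
                self.gene_set,
                es,
                n_perm=n_perm,
                seed=_derive_seed(seed, str(drug)),
                weight_exponent=self.weight_exponent,
                alternative=self.alternative,
            )
            rows.append({"drug_id": drug, "es": es, "p_nominal": p})
        df = pd.DataFrame(rows)
        if not df.empty:
            df["fdr"] = bh_fdr(df["p_nominal"].to_numpy())
        else:
            df["fdr"] = pd.Series(dtype=float)
        df["n_perm"] = n_perm
        return SignatureEnrichmentResults(self, df, n_perm=n_perm, seed=seed)


class SignatureEnrichmentResults:
    """Per-drug ES, permutation p, BH FDR and candidate tiers."""

    def __init__(
        self,
        model: SignatureEnrichment,
        frame: pd.DataFrame,
        n_perm: int,
        seed: int,
    ):
        self.model = model
        self._frame = frame
        self.n_perm = n_perm
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        return select_candidates(self._frame)

    def select(self, tiers: tuple[float, float] = _TIERS) -> pd.DataFrame:
        return select_candidates(self._frame, tiers)

    def candidates(self, fdr: float = 0.25) -> list[str]:
        df = self._frame
        return sorted(df.loc[df["fdr"] < fdr, "drug_id"])

    def summary(self) -> str:
        df = self.frame
        n25 = int((df["fdr"] < 0.25).sum())
        n10 = int((df["fdr"] < 0.1).sum())
        lines = [
            "Signature enrichment screen",
            "=" * 64,
            f"Profiles screened: {len(df)}   permutations: {self.n_perm}   "
            f"seed: {self.seed}",
            f"FDR < 0.25: {n25}   FDR < 0.1: {n10}",
            "-" * 64,
            df[["drug_id", "es", "p_nominal", "fdr", "tier"]].to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
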