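"""Degree-weighted network proximity between drug targets and disease genes.

The observed statistic is the closest weighted distance

    d(G, T) = (1/|T|) * sum over t in T of [ min over g in G of d(g, t) + w(t) ]

where d(g, t) is the unweighted shortest-path length, and the weight
w(t) = -ln(D + 1) (D the degree of t) applies only when the target t is
itself a disease gene, rewarding hub targets inside the disease set; for
all other targets w = 0.  Significance comes from a randomization null:
protein sets matched in size to the target set are drawn uniformly from
the network, scored identically, and the observed distance is converted
to a z-score

    z(G, T) = (d(G, T) - mu) / sigma

against that reference distribution.  Strongly negative z means the
drug's targets sit closer to the disease module than random protein sets
of the same size.

The :class:`NetworkProximity` model scores a whole drug–target map;
:class:`NetworkProximityResults` carries per-drug observed distances,
null moments, z-scores, and the distance-threshold screen.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidParameterError,
    NullDistributionError,
    ParseError,
    ScoringError,
)
from .network import UNREACHABLE, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DrugTargets",
    "DrugTargetMap",
    "NullDistribution",
    "ProximityResult",
    "target_weight",
    "closest_weighted_distance",
    "sample_null",
    "proximity_z",
    "screen_by_distance",
    "distance_density_summary",
    "NetworkProximity",
    "NetworkProximityResults",
    "read_drug_targets",
    "write_drug_targets",
]


# ---------------------------------------------------------------------------
# Containers


@dataclass
class DrugTargets:
    drug_id: str
    drug_name: str
    targets: set[str]


@dataclass
class DrugTargetMap:
    """Drug id -> (name, target symbols)."""

    drugs: dict[str, DrugTargets] = field(default_factory=dict)

    def add(self, drug_id: str, drug_name: str, targets: Iterable[str]) -> None:
        entry = self.drugs.setdefault(
            drug_id, DrugTargets(drug_id, drug_name, set())
        )
        entry.targets |= set(targets)

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self):
        return iter(self.drugs.values())

    def __getitem__(self, drug_id: str) -> DrugTargets:
        return self.drugs[drug_id]

    def all_targets(self, drug_ids: Iterable[str] | None = None) -> set[str]:
        ids = set(drug_ids) if drug_ids is not None else set(self.drugs)
        out: set[str] = set()
        for d in ids:
            out |= self.drugs[d].targets
        return out


@dataclass
class NullDistribution:
    """Reference distances of size-matched random protein sets."""

    sample_distances: np.ndarray
    mu: float
    sigma: float
    n_iter: int
    k: int
    seed: int


@dataclass
class ProximityResult:
    drug_id: str
    drug_name: str
    d_obs: float
    mu: float
    sigma: float
    z: float
    n_targets_mapped: int
    n_targets_dropped: int


# ---------------------------------------------------------------------------
# Core statistic


def target_weight(
    target: str, disease_set: Iterable[str], network: InteractionNetwork
) -> float:
    """Weight w(t) = -ln(D + 1) for disease-gene targets, else 0.

    D is the network degree of the target itself; the weight is always
    <= 0 and rewards targets that are hub members of the disease set.
    """
    if target not in set(disease_set):
        return 0.0
    return -math.log(network.degree(target) + 1)


def _node_contributions(
    network: InteractionNetwork, disease_set: set[str]
) -> dict[str, float]:
    """Per-node value min_g d(g, t) + w(t), UNREACHABLE where undefined.

    The minimum over disease genes comes from one multi-source BFS, and
    the weight depends only on the node, so each node's contribution to
    d(G, T) is a fixed number reusable across drugs and null draws.
    """
    dist = network.multi_source_distances(disease_set)
    contrib: dict[str, float] = {}
    for node, d in dist.items():
        if d == UNREACHABLE:
            contrib[node] = UNREACHABLE
        else:
            w = (
                -math.log(network.degree(node) + 1)
                if node in disease_set
                else 0.0
            )
            contrib[node] = d + w
    return contrib


def closest_weighted_distance(
    disease_set: Iterable[str],
    targets: Iterable[str],
    network: InteractionNetwork,
    _contrib: dict[str, float] | None = None,
) -> tuple[float, int, int]:
    """Observed distance d(G, T) with dropped-target accounting.

    Each target contributes min over disease genes of the hop distance,
    plus its weight.  Targets absent from the network or unreachable from
    every disease gene are dropped; |T| in the average is the number of
    contributing targets.  Returns ``(d_obs, n_mapped, n_dropped)``.

    Raises
    ------
    ScoringError
        If no target contributes.
    """
    G = set(disease_set)
    T = set(targets)
    if not G or not T:
        raise ScoringError("disease set and target set must be non-empty")
    contrib = _contrib if _contrib is not None else _node_contributions(network, G)
    values = []
    for t in T:
        c = contrib.get(t, UNREACHABLE)
        if c != UNREACHABLE:
            values.append(c)
    n_mapped = len(values)
    n_dropped = len(T) - n_mapped
    if n_mapped == 0:
        raise ScoringError(
            "no target maps into the network or is reachable from the disease set"
        )
    return float(np.sum(values) / n_mapped), n_mapped, n_dropped


def _derive_seed(seed: int, label: str) -> int:
    """Stable per-drug seed from (global seed, drug id); below 2**31."""
    digest = hashlib.blake2b(f"{seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _degree_bins(network: InteractionNetwork) -> dict[str, list[str]]:
    bins: dict[int, list[str]] = {}
    for n in network.graph.nodes:
        bins.setdefault(int(math.log2(max(network.degree(n), 1))), []).append(n)
    return {str(k): sorted(v) for k, v in bins.items()}


def sample_null(
    disease_set: Iterable[str],
    network: InteractionNetwork,
    k: int,
    n_iter: int = 10_000,
    seed: int = 0,
    mode: str = "uniform",
    _contrib: dict[str, float] | None = None,
    _match_nodes: Sequence[str] | None = None,
) -> NullDistribution:
    """Reference distribution of d(G, P) for random size-k protein sets.

    Each of ``n_iter`` draws selects ``k`` distinct nodes (uniformly by
    default; ``mode='degree_binned'`` matches the log2-degree bin profile
    of ``_match_nodes``) and scores them with the same closest-weighted
    statistic and dropping rules as observed target sets.  Draws in which
    every node is unreachable are redrawn.

    Raises
    ------
    NullDistributionError
        If the null has zero variance (degenerate network).
    InvalidParameterError
        For k < 1, n_iter < 100, or k >= node count.
    """
    G = set(disease_set)
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if n_iter < 100:
        raise InvalidParameterError(f"n_iter must be >= 100, got {n_iter}")
    n_nodes = network.number_of_nodes()
    if n_nodes <= k:
        raise InvalidParameterError(
            f"network must have more than k={k} nodes (has {n_nodes})"
        )
    contrib = _contrib if _contrib is not None else _node_contributions(network, G)
    nodes = sorted(network.graph.nodes)
    values = np.array([contrib[n] for n in nodes])
    rng = np.random.default_rng(seed)

    if mode == "degree_binned":
        if _match_nodes is None:
            raise InvalidParameterError(
                "degree_binned mode requires the target nodes to match"
            )
        draws = _degree_binned_draws(network, list(_match_nodes), n_iter, rng)
        sample = _score_draw_matrix(values, nodes, draws)
    elif mode == "uniform":
        sample = _uniform_null_sample(values, k, n_iter, rng)
    else:
        raise InvalidParameterError(f"unknown null mode {mode!r}")

    mu = float(np.mean(sample))
    sigma = float(np.std(sample, ddof=1))
    # a constant sample can acquire O(eps) spread from the mean's rounding
    if sigma <= 1e-12 * max(1.0, abs(mu)) or not np.isfinite(sigma):
        raise NullDistributionError(
            "null distribution is degenerate (zero variance)"
        )
    return NullDistribution(
        sample_distances=sample, mu=mu, sigma=sigma, n_iter=n_iter, k=k, seed=seed
    )


def _uniform_null_sample(
    values: np.ndarray, k: int, n_iter: int, rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Vectorised uniform draws of k distinct nodes, chunked for memory."""
    n = values.size
    out = np.empty(n_iter)
    pos = 0
    while pos < n_iter:
        m = min(chunk, n_iter - pos)
        # top-k of a random matrix row = a uniform k-subset without replacement
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        vals = values[idx]
        finite = np.isfinite(vals)
        cnt = finite.sum(axis=1)
        sums = np.where(finite, vals, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = sums / cnt
        # redraw any degenerate rows (all-unreachable draws) one by one
        for i in np.flatnonzero(cnt == 0):
            d[i] = _redraw_one(values, k, rng)
        out[pos : pos + m] = d
        pos += m
    return out


def _redraw_one(values: np.ndarray, k: int, rng: np.random.Generator,
                max_tries: int = 1000) -> float:
    for _ in range(max_tries):
        idx = rng.choice(values.size, size=k, replace=False)
        vals = values[idx]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            return float(vals.sum() / vals.size)
    raise NullDistributionError(
        "could not draw a reachable null protein set"
    )


def _degree_binned_draws(
    network: InteractionNetwork,
    match_nodes: list[str],
    n_iter: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    bins = _degree_bins(network)
    profile = [
        str(int(math.log2(max(network.degree(n), 1)))) for n in match_nodes
    ]
    draws = []
    for _ in range(n_iter):
        picked: set[str] = set()
        for b in profile:
            pool = [n for n in bins[b] if n not in picked]
            if not pool:  # bin exhausted; widen to all nodes
                pool = [n for n in network.graph.nodes if n not in picked]
            picked.add(pool[rng.integers(len(pool))])
        draws.append(sorted(picked))
    return draws


def _score_draw_matrix(
    values: np.ndarray, nodes: list[str], draws: list[list[str]]
) -> np.ndarray:
    index = {n: i for i, n in enumerate(nodes)}
    out = np.empty(len(draws))
    for i, draw in enumerate(draws):
        vals = values[[index[n] for n in draw]]
        vals = vals[np.isfinite(vals)]
        out[i] = vals.sum() / vals.size if vals.size else np.nan
    return out


def proximity_z(d_obs: float, null: NullDistribution) -> float:
    """z(G, T) = (d_obs - mu) / sigma against the reference distribution."""
    if null.sigma <= 0:
        raise NullDistributionError("null sigma must be positive")
    return (d_obs - null.mu) / null.sigma


def screen_by_distance(
    results: Iterable[ProximityResult] | Mapping[str, float],
    threshold: float = 1.0,
) -> list[str]:
    """Drugs whose raw weighted distance is strictly below the threshold.

    The screening statistic is d(G, T) itself (z-scores are reported
    separately); returned drug ids are sorted by ascending distance.
    """
    if isinstance(results, Mapping):
        pairs = list(results.items())
    else:
        pairs = [(r.drug_id, r.d_obs) for r in results]
    kept = [(d, drug) for drug, d in pairs if d < threshold]
    return [drug for d, drug in sorted(kept)]


def distance_density_summary(
    drug_distances: Sequence[float],
    reference_distances: Sequence[float],
    n_grid: int = 256,
) -> pd.DataFrame:
    """Gaussian-kernel density estimates of the two distance samples.

    Both densities are evaluated on a shared grid spanning the pooled
    range (padded by one bandwidth) and returned as a table with columns
    ``grid``, ``drug_density``, ``reference_density``.  Each column
    integrates to ~1 over the grid by construction of the KDE.
    """
    from scipy.stats import gaussian_kde

    drug = np.asarray(drug_distances, dtype=float)
    ref = np.asarray(reference_distances, dtype=float)
    if drug.size == 0 or ref.size == 0:
        raise InvalidParameterError("both distance samples must be non-empty")

    def _kde(x: np.ndarray):
        if np.ptp(x) == 0:  # degenerate sample: spike via tiny jitter scale
            x = x + np.linspace(-1e-9, 1e-9, x.size)
        return gaussian_kde(x)

    kde_drug, kde_ref = _kde(drug), _kde(ref)
    pad = max(kde_drug.factor * drug.std(), kde_ref.factor * ref.std(), 1e-9) * 3
    lo = min(drug.min(), ref.min()) - pad
    hi = max(drug.max(), ref.max()) + pad
    grid = np.linspace(lo, hi, n_grid)
    return pd.DataFrame(
        {
            "grid": grid,
            "drug_density": kde_drug(grid),
            "reference_density": kde_ref(grid),
        }
    )


# ---------------------------------------------------------------------------
# Model / Results


class NetworkProximity:
    """Proximity model for a drug–target map against a disease gene set.

    Parameters
    ----------
    network
        The merged interactome (distances and degrees come from here).
    disease_genes
        The disease gene set G.
    drug_targets
        A :class:`DrugTargetMap` of the drugs to score.
    """

    def __init__(
        self,
        network: InteractionNetwork,
        disease_genes: Iterable[str],
        drug_targets: DrugTargetMap,
    ):
        self.network = network
        self.disease_genes = set(disease_genes)
        if not self.disease_genes:
            raise InvalidParameterError("disease gene set is empty")
        self.drug_targets = drug_targets

    def fit(
        self,
        n_iter: int = 10_000,
        seed: int = 0,
        threshold: float = 1.0,
        null_mode: str = "uniform",
    ) -> "NetworkProximityResults":
        """Score every drug and fit its size-matched randomization null.

        Each drug gets its own random stream derived from
        ``(seed, drug_id)``, so results do not depend on drug order.
        Drugs with no mappable target are excluded with a logged warning.
        """
        contrib = _node_contributions(self.network, self.disease_genes)
        rows: list[ProximityResult] = []
        skipped: list[str] = []
        null_cache: dict[tuple[int, int], NullDistribution] = {}
        for drug in sorted(self.drug_targets.drugs):
            entry = self.drug_targets[drug]
            try:
                d_obs, n_mapped, n_dropped = closest_weighted_distance(
                    self.disease_genes, entry.targets, self.network,
                    _contrib=contrib,
                )
            except ScoringError as exc:
                logger.warning("drug %s excluded: %s", drug, exc)
                skipped.append(drug)
                continue
            drug_seed = _derive_seed(seed, drug)
            key = (n_mapped, drug_seed)
            if key not in null_cache:
                null_cache[key] = sample_null(
                    self.disease_genes,
                    self.network,
                    k=n_mapped,
                    n_iter=n_iter,
                    seed=drug_seed,
                    mode=null_mode,
                    _contrib=contrib,
                    _match_nodes=sorted(
                        t for t in entry.targets if t in self.network
                    ),
                )
            null = null_cache[key]
            rows.append(
                ProximityResult(
                    drug_id=drug,
                    drug_name=entry.drug_name,
                    d_obs=d_obs,
                    mu=null.mu,
                    sigma=null.sigma,
                    z=proximity_z(d_obs, null),
                    n_targets_mapped=n_mapped,
                    n_targets_dropped=n_dropped,
                )
            )
        return NetworkProximityResults(
            self, rows, skipped_drugs=skipped, threshold=threshold,
            n_iter=n_iter, seed=seed,
        )


class NetworkProximityResults:
    """Per-drug proximity estimates with their randomization nulls."""

    def __init__(
        self,
        model: NetworkProximity,
        results: list[ProximityResult],
        skipped_drugs: list[str],
        threshold: float,
        n_iter: int,
        seed: int,
    ):
        self.model = model
        self.results = results
        self.skipped_drugs = skipped_drugs
        self.threshold = threshold
        self.n_iter = n_iter
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "drug_id": r.drug_id,
                    "drug_name": r.drug_name,
                    "d_obs": r.d_obs,
                    "mu": r.mu,
                    "sigma": r.sigma,
                    "z": r.z,
                    "n_targets_mapped": r.n_targets_mapped,
                    "n_targets_dropped": r.n_targets_dropped,
                }
            for r in self.results
            ]
        )
        if df.empty:
            df = pd.DataFrame(
                columns=[
                    "drug_id", "drug_name", "d_obs", "mu", "sigma", "z",
                    "n_targets_mapped", "n_targets_dropped",
                ]
            )
        df["pass_screen"] = df["d_obs"] < self.threshold
        return df.sort_values("d_obs").reset_index(drop=True)

    def screen(self, threshold: float | None = None) -> list[str]:
        thr = self.threshold if threshold is None else threshold
        return screen_by_distance(self.results, thr)

    def density_summary(
        self, reference_distances: Sequence[float] | None = None
    ) -> pd.DataFrame:
        """Density table of observed distances vs a reference sample.

        Pass ``reference_distances`` explicitly to control the null;
        otherwise a fresh null matched to the median target-set size is
        drawn and used as the reference.
        """
        if reference_distances is None:
            ks = [r.n_targets_mapped for r in self.results]
            if not ks:
                raise InvalidParameterError("no scored drugs")
            null = sample_null(
                self.model.disease_genes,
                self.model.network,
                k=int(np.median(ks)),
                n_iter=max(self.n_iter, 100),
                seed=_derive_seed(self.seed, "__reference__"),
            )
            reference_distances = null.sample_distances
        return distance_density_summary(
            [r.d_obs for r in self.results], reference_distances
        )

    def plot_density(self, path: str | Path,
                     reference_distances: Sequence[float] | None = None) -> None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        table = self.density_summary(reference_distances)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.fill_between(table["grid"], table["drug_density"],
                        alpha=0.4, color="#d66", label="drugs")
        ax.fill_between(table["grid"], table["reference_density"],
                        alpha=0.4, color="#66d", label="reference")
        ax.axvline(self.threshold, ls="--", c="k", lw=0.8)
        ax.set_xlabel("weighted distance d(G, T)")
        ax.set_ylabel("density")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def summary(self) -> str:
        df = self.frame
        lines = [
            "Network proximity screen",
            "=" * 72,
            f"Drugs scored: {len(df)}   excluded: {len(self.skipped_drugs)}",
            f"Null iterations per drug: {self.n_iter}   seed: {self.seed}",
            f"Distance threshold: {self.threshold} "
            f"(pass: {int(df['pass_screen'].sum())})",
            "-" * 72,
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# I/O


def read_drug_targets(path: str | Path) -> DrugTargetMap:
    """Read a TSV ``drug_id drug_name target`` (one target per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"drug_id", "drug_name", "target"}
    if not expected <= set(df.columns):
        raise ParseError(
            f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}"
        )
    dtm = DrugTargetMap()
    for row in df.itertuples(index=False):
        dtm.add(row.drug_id, row.drug_name, [row.target])
    return dtm


def write_drug_targets(dtm: DrugTargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tdrug_name\ttarget\n")
        for drug_id in sorted(dtm.drugs):
            entry = dtm[drug_id]
            for t in sorted(entry.targets):
                fh.write(f"{drug_id}\t{entry.drug_name}\t{t}\n")
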