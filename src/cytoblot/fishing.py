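"""Subpopulation discovery by subsample spectral clustering ("cell fishing").

Bait selection: z-score each protein complex within its dataset, then
agglomerative hierarchical clustering (Euclidean distance, Ward linkage);
coherent sub-lineages of the treated dataset define bait groups.

Fishing: candidate cells (e.g., vehicle controls) are repeatedly partitioned
into subsamples of ~100 cells; each subsample is pooled with the bait and
clustered semi-supervised — Gaussian-kernel affinity, symmetric-normalized
graph Laplacian embedding, then a two-component Gaussian-mixture EM fit on the
row-normalized spectral coordinates. A round is valid when the bait stays
coherent (>= 90% of bait in one mixture component by default); candidates
assigned to the bait component are "captured". After many rounds (default
3000) candidates captured in >= 99.9% of their valid rounds are fished out:
they express the bait phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.mixture import GaussianMixture

__all__ = [
    "standardize",
    "hier_cluster",
    "FishingConfig",
    "FishingResult",
    "fishing_round",
    "cellfish",
]

COMPLEX_COLS = ["F", "MT", "IF"]


def standardize(matrix: pd.DataFrame, columns: list[str] | None = None,
                by: str | None = "condition") -> pd.DataFrame:
    """Z-score each protein-complex column to mean 0, sd 1.

    When ``by`` names a grouping column (default ``condition``), each dataset
    is standardized separately before any pooling — treated and control cells
    are scaled within their own dataset. Idempotent. Raises on a
    zero-variance column.
    """
    columns = columns or [c for c in COMPLEX_COLS if c in matrix.columns]
    out = matrix.copy()
    grouped = [(None, out)] if by is None or by not in out.columns else out.groupby(by, sort=False)
    for _, sub in grouped:
        for c in columns:
            v = sub[c].to_numpy(float)
            sd = v.std(ddof=0)
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"column {c!r} has zero variance within a dataset")
            out.loc[sub.index, c] = (v - v.mean()) / sd
    return out


def hier_cluster(matrix: pd.DataFrame, k: int | None = None,
                 height: float | None = None,
                 columns: list[str] | None = None):
    """Ward/Euclidean agglomerative clustering of the standardized matrix.

    Returns (labels, linkage_matrix). Cut by cluster count ``k`` or merge
    ``height``; ties inside the linkage are broken by scipy's deterministic
    ordering.
    """
    columns = columns or [c for c in COMPLEX_COLS if c in matrix.columns]
    X = matrix[columns].to_numpy(float)
    if len(X) < 2:
        raise ValueError("need >= 2 cells to cluster")
    Z = linkage(X, method="ward", metric="euclidean")
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        labels = fcluster(Z, t=2, criterion="maxclust")
    return labels, Z


@dataclass(frozen=True)
class FishingConfig:
    subsample_size: int = 100
    rounds: int = 3000
    capture_threshold: float = 0.999
    embed_dims: int = 2
    kernel_bandwidth: float | None = None  # None -> median pairwise distance
    bait_coherence: float = 0.9
    em_restarts: int = 5
    em_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.capture_threshold <= 1.0:
            raise ValueError("capture_threshold must be in (0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.subsample_size < 2:
            raise ValueError("subsample_size must be >= 2")


@dataclass
class FishingResult:
    candidates: list
    rounds: np.ndarray  # rounds participated per candidate
    valid_rounds: np.ndarray
    captures: np.ndarray
    capture_frequency: np.ndarray
    fished_out: list
    round_diagnostics: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.candidates,
                "rounds": self.rounds,
                "valid_rounds": self.valid_rounds,
                "captures": self.captures,
                "capture_frequency": self.capture_frequency,
                "fished_out": [c in set(self.fished_out) for c in self.candidates],
            }
        )


def _spectral_embedding(X: np.ndarray, dims: int, bandwidth: float | None) -> np.ndarray:
    """Gaussian-kernel affinity -> symmetric-normalized Laplacian -> top
    ``dims`` non-trivial eigenvectors.

    Eigenvector rows are used as-is (no per-row unit scaling): cells weakly
    connected to every cluster carry near-zero eigenvector mass and should
    stay near the origin with the bulk — rescaling such rows to the unit
    sphere assigns outliers an essentially random direction, which lets them
    co-cluster with a tight bait group round after round.
    """
    d = pdist(X)
    h = bandwidth if bandwidth is not None else float(np.median(d))
    if h <= 0:
        h = 1.0  # all points coincide; embedding is degenerate but defined
    W = np.exp(-squareform(d) ** 2 / (2.0 * h**2))
    deg = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    # eigenvectors of D^-1/2 W D^-1/2, largest first; index 0 is the trivial one
    M = W * np.outer(inv_sqrt, inv_sqrt)
    n = len(M)
    vals, vecs = eigh(M, subset_by_index=[max(n - dims - 1, 0), n - 1])
    return vecs[:, ::-1][:, 1 : dims + 1]


def fishing_round(
    bait: np.ndarray,
    candidates: np.ndarray,
    config: FishingConfig,
    round_seed: int,
) -> tuple[np.ndarray, bool]:
    """One semi-supervised clustering round on bait ∪ candidate rows.

    Returns (captured_mask over candidates, valid) where a round is valid when
    at least ``bait_coherence`` of the bait lands in a single mixture
    component and the EM fit converged.
    """
    bait = np.asarray(bait, float)
    candidates = np.asarray(candidates, float)
    pooled = np.vstack([bait, candidates])
    if len(pooled) < config.embed_dims + 2:
        raise ValueError("pooled sample too small for the embedding")
    emb = _spectral_embedding(pooled, config.embed_dims, config.kernel_bandwidth)
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=config.em_restarts,
        init_params="k-means++",
        tol=config.em_tol,
        reg_covar=1e-9,
        max_iter=300,
        random_state=int(round_seed) % (2**31 - 1),
    )
    try:
        labels = gmm.fit_predict(emb)
    except ValueError:
        return np.zeros(len(candidates), dtype=bool), False
    if not gmm.converged_:
        return np.zeros(len(candidates), dtype=bool), False
    nb = len(bait)
    bait_labels = labels[:nb]
    counts = np.bincount(bait_labels, minlength=2)
    bait_comp = int(np.argmax(counts))
    coherence = counts[bait_comp] / nb
    valid = bool(coherence >= config.bait_coherence)
    captured = labels[nb:] == bait_comp if valid else np.zeros(len(candidates), dtype=bool)
    return captured, valid


def _partition(n: int, subsample_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into ceil(n/size) near-equal groups; every index
    appears exactly once."""
    perm = rng.permutation(n)
    n_groups = max(1, int(np.ceil(n / subsample_size)))
    return [np.sort(g) for g in np.array_split(perm, n_groups)]


def cellfish(
    bait_matrix: pd.DataFrame,
    candidate_matrix: pd.DataFrame,
    config: FishingConfig,
    columns: list[str] | None = None,
) -> FishingResult:
    """Run the full fishing procedure.

    ``bait_matrix`` and ``candidate_matrix`` hold *standardized* complex
    expression rows (see :func:`standardize`); candidate ids must be disjoint
    from bait ids. Capture frequency is captures / valid rounds participated;
    candidates at or above ``capture_threshold`` are fished out. Fully
    reproducible from ``config.seed``.
    """
    columns = columns or [c for c in COMPLEX_COLS if c in bait_matrix.columns]
    bait_ids = set(bait_matrix["cell_id"]) if "cell_id" in bait_matrix.columns else set()
    cand_ids = list(candidate_matrix["cell_id"]) if "cell_id" in candidate_matrix.columns else list(range(len(candidate_matrix)))
    if bait_ids & set(cand_ids):
        raise ValueError("candidate cells must be disjoint from bait cells")
    B = bait_matrix[columns].to_numpy(float)
    C = candidate_matrix[columns].to_numpy(float)
    n = len(C)
    if n == 0:
        raise ValueError("no candidate cells")

    rng = np.random.default_rng(config.seed)
    participated = np.zeros(n, dtype=int)
    valid_participated = np.zeros(n, dtype=int)
    captures = np.zeros(n, dtype=int)
    diags = []
    for rnd in range(config.rounds):
        groups = _partition(n, config.subsample_size, rng)
        for gi, grp in enumerate(groups):
            participated[grp] += 1
            seed = int(rng.integers(0, 2**31 - 1))
            captured, valid = fishing_round(B, C[grp], config, seed)
            if valid:
                valid_participated[grp] += 1
                captures[grp[captured]] += 1
            diags.append(dict(round=rnd, group=gi, size=len(grp) + len(B), valid=valid,
                              n_captured=int(captured.sum())))

    with np.errstate(invalid="ignore"):
        freq = np.where(valid_participated > 0, captures / np.maximum(valid_participated, 1), 0.0)
    fished = [cand_ids[i] for i in range(n)
              if valid_participated[i] > 0 and freq[i] >= config.capture_threshold]
    return FishingResult(
        candidates=cand_ids,
        rounds=participated,
        valid_rounds=valid_participated,
        captures=captures,
        capture_frequency=freq,
        fished_out=fished,
        round_diagnostics=pd.DataFrame(diags),
    )
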