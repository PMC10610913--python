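"""Per-residue collapse of the enrichment matrix and residue classification.

The per-residue summary is the median RE over the scored missense cells of a
column (stop codons and masked cells excluded).  The distribution of medians
in a selection screen is bimodal — residues whose mutation broadly abolishes
aggregation versus tolerant residues — and is split by Otsu's method, the
classical histogram threshold maximizing between-class variance.  Residues at
or below the threshold form the inhibitory set, rendered as maximal runs
("29 to 30" style).  A 2-D stochastic-neighbour embedding of each residue's
20-substitution profile exposes mutation covariance between residues.
"""

from __future__ import annotations

import re as _re
from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

from .enrichment import DISPLAY_ORDER, EnrichmentMatrix


def residue_medians(matrix: EnrichmentMatrix) -> dict[int, float]:
    """Median scored missense RE per position; all-masked positions omitted."""
    out: dict[int, float] = {}
    for j, pos in enumerate(matrix.positions):
        col = matrix.values[:, j]
        vals = col[np.isfinite(col)]
        if vals.size:
            out[pos] = float(np.median(vals))
    return out


def otsu_threshold(values, bins: int = 256) -> float:
    """Otsu threshold of a continuous sample.

    The sample is histogrammed into ``bins`` equal-width bins over its range
    and the inter-bin edge maximizing the between-class variance is returned
    (first edge on ties).  Classification convention downstream is inclusive:
    class "low" is value <= threshold.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("Otsu threshold needs >= 2 distinct finite values")
    hist, edges = np.histogram(x, bins=bins, range=(x.min(), x.max()))
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(p)                      # weight of class <= bin k
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        # between-class variance for a cut after bin k (k = 0..bins-2)
        sigma_b = (mu_total * w0 - m) ** 2 / (w0 * (1 - w0))
    sigma_b = sigma_b[:-1]
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1])


@dataclass
class ResidueClassification:
    medians: dict[int, float]
    threshold: float
    inhibitory: set[int]
    intervals: list[tuple[int, int]]

    def render_intervals(self) -> str:
        """Paper-style rendering: ``2, 27, 29 to 30, 33``."""
        parts = [
            f"{a}" if a == b else f"{a} to {b}" for a, b in self.intervals
        ]
        return ", ".join(parts)


def parse_intervals(text: str) -> set[int]:
    """Inverse of :meth:`ResidueClassification.render_intervals`."""
    residues: set[int] = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        m = _re.match(r"^(\d+)(?:\s+to\s+(\d+))?$", part)
        if not m:
            raise ValueError(f"cannot parse interval {part!r}")
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) else a
        residues.update(range(a, b + 1))
    return residues


def merge_runs(positions) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers."""
    pos = sorted(set(positions))
    runs: list[tuple[int, int]] = []
    for p in pos:
        if runs and p == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], p)
        else:
            runs.append((p, p))
    return runs


def classify(
    medians: dict[int, float], threshold: float
) -> ResidueClassification:
    """Inclusive split: inhibitory = {p : median[p] <= threshold}."""
    if not medians:
        raise ValueError("empty median map")
    inhibitory = {p for p, m in medians.items() if m <= threshold}
    return ResidueClassification(
        medians=dict(medians),
        threshold=threshold,
        inhibitory=inhibitory,
        intervals=merge_runs(inhibitory),
    )


def classify_matrix(
    matrix: EnrichmentMatrix, bins: int = 256
) -> ResidueClassification:
    """Median collapse + Otsu + inclusive classification, in one call."""
    med = residue_medians(matrix)
    thr = otsu_threshold(list(med.values()), bins=bins)
    return classify(med, thr)


@dataclass
class EmbeddingResult:
    positions: list[int]
    features: np.ndarray        # positions x 20, missing cells zero-filled
    coords: np.ndarray          # positions x 2
    perplexity: float
    metric: str
    seed: int


def embed_profiles(
    matrix: EnrichmentMatrix, perplexity: float = 30.0, seed: int = 0
) -> EmbeddingResult:
    """t-SNE of per-residue 20-substitution profiles (Euclidean metric).

    Positions with no scored missense cell at all are excluded; within an
    included position, masked cells are zero-filled.  The exact-gradient
    solver is used (N ~ 10^2) with PCA initialization, so a fixed seed yields
    identical coordinates on rerun.
    """
    scored = sorted(residue_medians(matrix))
    if len(scored) < 3 * perplexity:
        raise ValueError(
            f"{len(scored)} scored positions < 3 x perplexity ({perplexity}); "
            "lower the perplexity"
        )
    cols = [matrix.positions.index(p) for p in scored]
    feats = matrix.values[:, cols].T.copy()
    feats[~np.isfinite(feats)] = 0.0
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        metric="euclidean",
        method="exact",
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(feats)
    return EmbeddingResult(scored, feats, coords, perplexity, "euclidean", seed)


def gatekeeper_profile(matrix: EnrichmentMatrix, substitution: str) -> np.ndarray:
    """RE profile of one substitution across positions (NaN where masked).

    Named for "aggregation gatekeeper" residues (R, P, W ...) whose
    substitution profiles flag aggregation-core regions.
    """
    return matrix.row(substitution)
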