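"""Feature vectors from displacement fields, 2-D PCA, and temporal profiles.

Each frame's displacement field is flattened to a fixed-order feature vector
(u then v over the lattice, row-major); pooled vectors from all participants
and labels are centered on the cohort mean and decomposed with PCA.  The two
leading components give a planar embedding in which neutral frames sit near
the origin (almost no motion) and happy/sad frames separate.  Temporal
profiles track the lattice-mean displacement magnitude over a viewing block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import LABELS, DisplacementField
from .session import Session


def flatten_field(field: DisplacementField) -> np.ndarray:
    """Fixed-order feature vector: u then v over the lattice, row-major.

    Invalid (boundary-dropped) lattice points are imputed as zero so every
    frame of a session yields the same dimension; the imputation count is
    available as ``field.valid.size - field.n_valid``.
    """
    u = np.nan_to_num(field.u, nan=0.0).ravel()
    v = np.nan_to_num(field.v, nan=0.0).ravel()
    return np.concatenate([u, v])


def unflatten(vector: np.ndarray, field: DisplacementField) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`flatten_field` given the originating lattice."""
    shape = field.lattice_shape
    n = shape[0] * shape[1]
    return vector[:n].reshape(shape), vector[n:].reshape(shape)


@dataclass(frozen=True)
class FrameFeatureVector:
    participant_id: str
    frame_index: int
    label: str
    values: np.ndarray

    @property
    def dimension(self) -> int:
        return len(self.values)


def session_features(session: Session) -> list[FrameFeatureVector]:
    """One feature vector per computed frame of a session, in frame order."""
    out = []
    for i in sorted(session.fields):
        f = session.fields[i]
        out.append(
            FrameFeatureVector(
                participant_id=session.participant_id,
                frame_index=i,
                label=session.frames[i].label,
                values=flatten_field(f),
            )
        )
    return out


@dataclass(frozen=True)
class Embedding2D:
    """Planar PCA embedding with the full explained-variance spectrum."""

    coords: np.ndarray  # (n, 2)
    explained_variance_ratio: np.ndarray  # all components, non-increasing
    components: np.ndarray  # (2, d) sign-fixed leading eigenvectors
    mean: np.ndarray  # (d,) pooled centering vector

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean) @ self.components.T


def _fix_signs(components: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-magnitude entry positive (deterministic)."""
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(len(components)), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None], signs


def fit_project(vectors: Sequence[np.ndarray] | np.ndarray) -> Embedding2D:
    """Centered PCA of pooled feature vectors; top-2 projections returned.

    The full explained-variance spectrum (summing to 1) is retained so the
    share captured by the plane is inspectable.  Component signs follow a
    deterministic convention (largest-magnitude loading positive), since PCA
    axes are otherwise sign-arbitrary.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("at least three equal-dimension vectors are required")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("zero-variance input: PCA is undefined")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    comps, signs = _fix_signs(pca.components_[:2])
    coords = scores[:, :2] * signs[None, :]
    return Embedding2D(
        coords=coords,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        components=comps,
        mean=pca.mean_.copy(),
    )


def participant_emotion_means(
    embedding: Embedding2D,
    labels: Sequence[str],
    participant_ids: Sequence[str],
) -> pd.DataFrame:
    """Mean (PC1, PC2) per participant per emotion, plus ordering relations.

    Returns a tidy frame with columns participant_id, label, pc1, pc2, n;
    rows exist only for non-empty groups.  The helper
    :func:`happy_sad_orderings` derives per-participant sign relations.
    """
    df = pd.DataFrame(
        {
            "participant_id": list(participant_ids),
            "label": list(labels),
            "pc1": embedding.coords[:, 0],
            "pc2": embedding.coords[:, 1],
        }
    )
    out = (
        df.groupby(["participant_id", "label"], sort=True)
        .agg(pc1=("pc1", "mean"), pc2=("pc2", "mean"), n=("pc1", "size"))
        .reset_index()
    )
    return out


def happy_sad_orderings(means: pd.DataFrame) -> pd.DataFrame:
    """Per-participant sign of (happy mean - sad mean) on each component."""
    piv = means.pivot(index="participant_id", columns="label", values=["pc1", "pc2"])
    out = pd.DataFrame(index=piv.index)
    for pc in ("pc1", "pc2"):
        out[f"happy_gt_sad_{pc}"] = piv[(pc, "happy")] > piv[(pc, "sad")]
    return out.reset_index()


def temporal_profile(session: Session, label: str) -> pd.DataFrame:
    """Lattice-mean displacement magnitude per frame of one emotion block.

    Returns columns participant_id, label, block_time (seconds since block
    start), frame_index, mean_magnitude.  Image-onset times fall every 10 s
    under the default schedule.
    """
    rows = []
    block_start = {}
    for pos, b in enumerate(session.block_ids):
        block_start.setdefault(b, pos)
    for i in sorted(session.fields):
        if session.frames[i].label != label:
            continue
        b = session.block_ids[i]
        start = block_start[b]
        mag = session.fields[i].magnitude
        rows.append(
            {
                "participant_id": session.participant_id,
                "label": label,
                "block_time": float(i - start),
                "frame_index": i,
                "mean_magnitude": float(np.nanmean(mag)),
            }
        )
    return pd.DataFrame(rows)


def cohort_profile(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean profile across participants, aligned on block time."""
    allp = pd.concat(profiles, ignore_index=True)
    out = (
        allp.groupby(["label", "block_time"], sort=True)["mean_magnitude"]
        .mean()
        .reset_index()
    )
    return out
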