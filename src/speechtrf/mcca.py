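"""Multiway canonical correlation analysis (MCCA) for group denoising.

Summed-covariance formulation: each subject's (time x channel) data is reduced
to ``n_pc`` whitened principal components; the whitened components of all
subjects are stacked along channels and a second PCA of the stack yields
canonical components ordered by inter-subject shared variance. Denoising
projects a subject's data into canonical space, truncates to the leading
``n_cc`` components and back-projects to channel space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import EEGRecording

__all__ = ["MCCAModel", "mcca_fit", "mcca_denoise"]


@dataclass
class MCCAModel:
    subject_ids: list[str]
    means: dict[str, np.ndarray]          # per-subject channel means
    whiteners: dict[str, np.ndarray]      # channels x n_pc_s
    mix: np.ndarray                       # (sum n_pc_s) x K stacked rotation
    blocks: dict[str, slice]              # subject rows of `mix`
    eigenvalues: np.ndarray
    n_pc: int
    n_cc: int

    @property
    def n_components(self) -> int:
        return self.mix.shape[1]

    def subject_transform(self, subject_id: str) -> np.ndarray:
        """Channels -> canonical components for one subject."""
        W = self.whiteners[subject_id]
        return W @ self.mix[self.blocks[subject_id]]

    def canonical_scores(self, data_by_subject: dict[str, np.ndarray]) -> np.ndarray:
        """Summed canonical components (samples x K) of a group dataset."""
        y = None
        for sid, x in data_by_subject.items():
            xi = (x.T - self.means[sid]) @ self.subject_transform(sid)
            y = xi if y is None else y + xi
        return y


def _as_matrix(rec) -> np.ndarray:
    """samples x channels from an EEGRecording, list of trials, or array."""
    if isinstance(rec, EEGRecording):
        return rec.data.T
    if isinstance(rec, (list, tuple)):
        return np.concatenate([_as_matrix(r) for r in rec], axis=0)
    arr = np.asarray(rec, dtype=float)
    return arr.T  # channels x samples convention


def mcca_fit(
    recordings: dict[str, object] | list,
    n_pc: int = 40,
    n_cc: int = 110,
) -> MCCAModel:
    """Fit MCCA across time-aligned subjects.

    Parameters
    ----------
    recordings : mapping subject_id -> EEGRecording / trial list / channels x
        samples array (all with identical sample counts), or a plain list.
    n_pc : principal components kept per subject before stacking (reduced with
        a warning on rank deficiency).
    n_cc : canonical components retained when denoising.
    """
    if not isinstance(recordings, dict):
        recordings = {f"s{i:03d}": r for i, r in enumerate(recordings)}
    if len(recordings) < 2:
        raise ValueError("MCCA needs at least 2 subjects")

    whiteners: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    blocks: dict[str, slice] = {}
    stacked = []
    start = 0
    n_samples = None
    for sid, rec in recordings.items():
        X = _as_matrix(rec)
        if n_samples is None:
            n_samples = X.shape[0]
        elif X.shape[0] != n_samples:
            raise ValueError("subjects must be time-aligned (equal lengths)")
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
        rank = int((s > tol).sum())
        p = min(n_pc, rank)
        if p < n_pc:
            warnings.warn(
                f"subject {sid}: rank {rank} < n_pc {n_pc}; reducing to {p}"
            )
        # whitened scores Z = Xc W have unit-variance columns
        W = Vt[:p].T / s[:p] * np.sqrt(n_samples)
        whiteners[sid] = W
        means[sid] = mu
        blocks[sid] = slice(start, start + p)
        start += p
        stacked.append(Xc @ W)

    Z = np.concatenate(stacked, axis=1)
    # PCA of the stacked whitened data: eigenvectors of Z'Z order components
    # by the variance shared across subjects.
    _, sz, Vzt = np.linalg.svd(Z, full_matrices=False)
    mix = Vzt.T
    eig = sz**2 / n_samples
    n_cc = min(n_cc, mix.shape[1])
    return MCCAModel(
        subject_ids=list(recordings),
        means=means,
        whiteners=whiteners,
        mix=mix,
        blocks=blocks,
        eigenvalues=eig,
        n_pc=n_pc,
        n_cc=n_cc,
    )


def mcca_denoise(
    rec: EEGRecording | np.ndarray,
    model: MCCAModel,
    subject_id: str | None = None,
    n_cc: int | None = None,
):
    """Truncated canonical back-projection of one subject's recording.

    With ``n_cc`` equal to the total number of canonical components this is
    the subject's rank-``n_pc`` PCA reconstruction.
    """
    if subject_id is None:
        if isinstance(rec, EEGRecording) and rec.subject_id:
            subject_id = rec.subject_id
        else:
            raise ValueError("subject_id required")
    if subject_id not in model.blocks:
        raise KeyError(f"subject {subject_id!r} not in fitted model")
    K = model.n_cc if n_cc is None else min(n_cc, model.n_components)
    A = model.subject_transform(subject_id)[:, :K]
    X = _as_matrix(rec) - model.means[subject_id]
    Xhat = (X @ A) @ np.linalg.pinv(A) + model.means[subject_id]
    out = Xhat.T
    if isinstance(rec, EEGRecording):
        return rec.with_data(out)
    return out
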