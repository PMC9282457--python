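"""Question-grouping via PCA and varimax rotation.

The biomarker item subsets are not hand-picked: the correlation structure of
complete patient-days (all 11 questions answered) is decomposed by principal
component analysis, components with eigenvalue > 1 are retained, varimax
rotation brings them toward simple structure, and each question is assigned
to the factor on which it loads most strongly. Factors are then merged into
named biomarkers (by default factors 1 and 3 into the wellbeing index,
factor 2 into the motivation/self-confidence index).

PCA is performed on the correlation matrix, so eigenvalues sum to the number
of variables and loadings are scaled so each component's squared loadings
sum to its eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .coding import QUESTIONS

__all__ = [
    "LoadingsMatrix",
    "BiomarkerDefinition",
    "DEFAULT_MERGE_MAP",
    "select_complete_days",
    "principal_components",
    "varimax_rotate",
    "assign_questions",
]

#: Default factor -> biomarker merge (1-based factor indices).
DEFAULT_MERGE_MAP: dict[str, list[int]] = {"WeBe-i": [1, 3], "MotSC-i": [2]}


@dataclass
class LoadingsMatrix:
    """Loadings of variables on retained components/factors.

    Attributes
    ----------
    loadings : pandas.DataFrame
        Variables x retained components; squared loadings per component sum
        to that component's eigenvalue (unrotated case).
    eigenvalues : numpy.ndarray
        Eigenvalues of the retained components, non-increasing.
    explained_pct : numpy.ndarray
        Percent of total variance explained per retained component.
    full_spectrum : numpy.ndarray
        All eigenvalues of the correlation matrix (sum = n variables).
    rotation : numpy.ndarray | None
        Orthonormal rotation applied, if any.
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    full_spectrum: np.ndarray
    rotation: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class BiomarkerDefinition:
    """A named biomarker and the ordered question subset that feeds it."""

    name: str
    questions: tuple[str, ...]


def select_complete_days(q_table: pd.DataFrame) -> pd.DataFrame:
    """Matrix of complete patient-days: one row per (patient, date) with all
    11 questions answered, columns in canonical question order."""
    wide = q_table.pivot_table(
        index=["patient_id", "date"], columns="question", values="value"
    )
    for q in QUESTIONS:
        if q not in wide.columns:
            wide[q] = np.nan
    wide = wide[list(QUESTIONS)]
    return wide.dropna(how="any")


def principal_components(matrix: pd.DataFrame | np.ndarray, k: int | None = None) -> LoadingsMatrix:
    """Eigen-decompose the correlation matrix of the columns.

    When ``k`` is None, components are retained by the eigenvalue > 1
    criterion (at least one component is always kept).

    Raises
    ------
    ValueError
        On a zero-variance column, or fewer rows than retained components.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = [f"v{i}" for i in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("matrix must have no missing cells")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = names[int(np.nonzero(sd == 0)[0][0])]
        raise ValueError(f"column {bad!r} has zero variance")

    corr = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    if k is None:
        k = max(1, int(np.sum(eigval > 1.0)))
    if X.shape[0] < k:
        raise ValueError(f"need at least {k} rows, got {X.shape[0]}")

    loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
    # sign convention: largest |loading| per component positive
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]
    return LoadingsMatrix(
        loadings=pd.DataFrame(
            loadings, index=names, columns=[f"PC{j + 1}" for j in range(k)]
        ),
        eigenvalues=eigval[:k],
        explained_pct=100.0 * eigval[:k] / eigval.sum(),
        full_spectrum=eigval,
    )


def varimax_rotate(loadings: LoadingsMatrix, k: int | None = None) -> LoadingsMatrix:
    """Orthogonal varimax rotation with Kaiser row-normalization.

    Rows are scaled to unit communality before rotation and scaled back
    after; column signs are fixed so each factor's largest-magnitude loading
    is positive. The rotation matrix is orthonormal, so per-row communality
    is preserved.

    Raises
    ------
    ValueError
        If fewer than 2 components are available (rotation undefined).
    """
    A = loadings.loadings.to_numpy(dtype=float)
    if k is not None:
        A = A[:, :k]
    if A.shape[1] < 2:
        raise ValueError("varimax rotation requires at least 2 components")

    h = np.sqrt((A**2).sum(axis=1))
    if (h == 0).any():
        raise ValueError("zero-communality row; cannot Kaiser-normalize")
    An = A / h[:, None]
    with warnings.catch_warnings():
        # the GPA iteration logs log10(criterion step), which is -inf at an
        # exact optimum (already-simple structure)
        warnings.simplefilter("ignore", RuntimeWarning)
        Rn, T = rotate_factors(An, "varimax", tol=1e-6, max_tries=1000)
    R = Rn * h[:, None]

    signs = np.ones(R.shape[1])
    for j in range(R.shape[1]):
        if R[np.argmax(np.abs(R[:, j])), j] < 0:
            signs[j] = -1.0
    R = R * signs
    T = T * signs

    return LoadingsMatrix(
        loadings=pd.DataFrame(
            R,
            index=loadings.loadings.index,
            columns=[f"Factor{j + 1}" for j in range(R.shape[1])],
        ),
        eigenvalues=loadings.eigenvalues[: R.shape[1]].copy(),
        explained_pct=loadings.explained_pct[: R.shape[1]].copy(),
        full_spectrum=loadings.full_spectrum.copy(),
        rotation=T,
    )


def assign_questions(
    rotated: LoadingsMatrix | pd.DataFrame,
    merge_map: dict[str, list[int]] | None = None,
) -> list[BiomarkerDefinition]:
    """Assign each question to its strongest factor, then merge factors.

    Each question goes to the factor with the largest absolute rotated
    loading (ties broken toward the lowest factor index); ``merge_map``
    groups 1-based factor indices into named biomarkers.

    Raises
    ------
    ValueError
        If a factor index in the map is out of range.
    """
    L = rotated.loadings if isinstance(rotated, LoadingsMatrix) else rotated
    k = L.shape[1]
    if merge_map is None:
        merge_map = DEFAULT_MERGE_MAP if k == 3 else {f"F{j + 1}": [j + 1] for j in range(k)}
    for name, idxs in merge_map.items():
        for i in idxs:
            if not (1 <= i <= k):
                raise ValueError(f"{name!r}: factor index {i} out of range 1..{k}")

    abs_load = np.abs(L.to_numpy(dtype=float))
    best = abs_load.argmax(axis=1) + 1  # argmax takes the lowest index on ties

    defs = []
    for name, idxs in merge_map.items():
        members = tuple(
            q for q, b in zip(L.index, best) if b in idxs
        )
        defs.append(BiomarkerDefinition(name=name, questions=members))
    return defs
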