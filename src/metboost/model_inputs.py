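"""Learner input tables: E, G, G+E and GEI constructions.

Every construction starts from the BLUE table (Env, Hybrid, y) and joins
numeric features onto it, always carrying the field location (environment
name without the year) as a categorical column:

* **E** — the environmental matrix left-joined on Env (no SVD);
* **G** — the first k component scores of the relationship matrix's SVD,
  joined on Hybrid;
* **G+E** — environmental features and the hybrid's relationship-matrix row
  concatenated per record, then reduced to k SVD components;
* **GEI** — the Kronecker product X = E (x) G, whose SVD is computed in
  factorized form: SVD(E (x) G) = (U_E (x) U_G)(S_E (x) S_G)(V_E (x) V_G)',
  so the top-k scores are assembled from the two small factor SVDs without
  ever materializing the (n q) x (m q) product.  Row (i, j) of the score
  matrix belongs to environment i and hybrid j and is joined by (Env, Hybrid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import KeyMismatchError
from .linalg import svd_decompose
from .utils import field_location

KEY_COLUMNS = ["Env", "Hybrid", "Field_Location", "y"]


@dataclass
class ModelInput:
    kind: str  # "E" | "G" | "G+E" | "GEI"
    grm_kind: str  # "A" | "D" | "none"
    table: pd.DataFrame  # KEY_COLUMNS + numeric feature columns
    svd_components: int  # components actually kept (0 for E)
    feature_cols: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.feature_cols:
            self.feature_cols = [
                c for c in self.table.columns if c not in KEY_COLUMNS
            ]

    @property
    def model_name(self) -> str:
        if self.kind in ("E",):
            return "E"
        suffix = {"G": "", "G+E": "+E", "GEI": "EI"}[self.kind]
        return f"G({self.grm_kind}){suffix}"


def _base_table(blues: pd.DataFrame) -> pd.DataFrame:
    out = blues[["Env", "Hybrid", "y"]].copy()
    out["Field_Location"] = out["Env"].map(field_location)
    return out[["Env", "Hybrid", "Field_Location", "y"]]


def _check_envs(blues, env_matrix):
    missing = sorted(set(blues["Env"]) - set(env_matrix.index))
    if missing:
        raise KeyMismatchError("BLUE environments absent from environmental matrix", missing)


def _check_hybrids(blues, grm):
    missing = sorted(set(blues["Hybrid"]) - set(grm.matrix.index))
    if missing:
        raise KeyMismatchError("BLUE hybrids absent from relationship matrix", missing)


def _effective_k(k: int, available: int, what: str) -> int:
    if k > available:
        warnings.warn(f"{what}: only {available} components available, reducing k={k}")
        return available
    return int(k)


def build_E(blues: pd.DataFrame, env_matrix: pd.DataFrame) -> ModelInput:
    """Environmental model input: env features joined on Env, no reduction.

    All features are constant within an environment, so downstream
    predictions are necessarily identical for every hybrid of an environment.
    """
    _check_envs(blues, env_matrix)
    table = _base_table(blues).join(env_matrix, on="Env")
    return ModelInput("E", "none", table, svd_components=0)


def build_G(blues: pd.DataFrame, grm, k: int = 100) -> ModelInput:
    """Genetic model input: top-k SVD scores of the GRM joined on Hybrid."""
    _check_hybrids(blues, grm)
    G = grm.matrix.to_numpy()
    U, s, _ = svd_decompose(G)
    k = _effective_k(k, len(s), "G")
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=grm.matrix.index,
        columns=[f"g_svd_{j + 1:03d}" for j in range(k)],
    )
    table = _base_table(blues).join(scores, on="Hybrid")
    return ModelInput("G", _grm_label(grm), table, svd_components=k)


def build_GplusE(
    blues: pd.DataFrame, env_matrix: pd.DataFrame, grm, k: int = 100
) -> ModelInput:
    """Additive combination: concatenated (env features | GRM row) per record,
    reduced to k SVD components."""
    _check_envs(blues, env_matrix)
    _check_hybrids(blues, grm)
    base = _base_table(blues)
    E = env_matrix.to_numpy(dtype=float)
    env_pos = {e: i for i, e in enumerate(env_matrix.index)}
    hyb_pos = {h: i for i, h in enumerate(grm.matrix.index)}
    wide = np.hstack(
        [
            E[[env_pos[e] for e in base["Env"]]],
            grm.matrix.to_numpy()[[hyb_pos[h] for h in base["Hybrid"]]],
        ]
    )
    # env features can carry NaN (e.g. missing lagged yields); SVD needs a
    # complete matrix, so impute column means (all-NaN columns become 0)
    if np.isnan(wide).any():
        with np.errstate(invalid="ignore"):
            means = np.nanmean(wide, axis=0)
        means = np.nan_to_num(means)
        nan_r, nan_c = np.where(np.isnan(wide))
        wide[nan_r, nan_c] = means[nan_c]
    U, s, _ = svd_decompose(wide)
    k = _effective_k(k, int(np.sum(s > 0)) or 1, "G+E")
    scores = U[:, :k] * s[:k]
    table = pd.concat(
        [
            base.reset_index(drop=True),
            pd.DataFrame(
                scores, columns=[f"ge_svd_{j + 1:03d}" for j in range(k)]
            ),
        ],
        axis=1,
    )
    return ModelInput("G+E", _grm_label(grm), table, svd_components=k)


def kronecker_svd_scores(
    env_matrix: pd.DataFrame, grm, k: int = 100
) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k left-singular scores of X = E (x) G without materializing X.

    Singular values of the Kronecker product are all pairwise products
    s_a * t_b of the factor singular values; the score of (environment i,
    hybrid j) on component (a, b) is U_E[i,a] * U_G[j,b] * s_a * t_b.
    Returns a DataFrame indexed by (Env, Hybrid) covering every combination,
    plus the kept singular values.
    """
    E = env_matrix.to_numpy(dtype=float)
    if np.isnan(E).any():
        with np.errstate(invalid="ignore"):
            means = np.nan_to_num(np.nanmean(E, axis=0))
        nan_r, nan_c = np.where(np.isnan(E))
        E[nan_r, nan_c] = means[nan_c]
    G = grm.matrix.to_numpy()
    U_E, s_E, _ = svd_decompose(E)
    U_G, s_G, _ = svd_decompose(G)
    prod = np.outer(s_E, s_G)  # (a, b) -> s_a * t_b
    flat = prod.ravel()
    k = _effective_k(k, len(flat), "GEI")
    top = np.argsort(-flat, kind="stable")[:k]
    a_idx, b_idx = np.unravel_index(top, prod.shape)
    # scores factorize: (U_E[:, a] * s) kron-expanded against U_G[:, b]
    left = U_E[:, a_idx] * flat[top]  # n x k
    right = U_G[:, b_idx]  # q x k
    n, q = len(env_matrix.index), len(grm.matrix.index)
    scores = (left[:, None, :] * right[None, :, :]).reshape(n * q, k)
    index = pd.MultiIndex.from_product(
        [env_matrix.index, grm.matrix.index], names=["Env", "Hybrid"]
    )
    cols = [f"gei_svd_{j + 1:03d}" for j in range(k)]
    return pd.DataFrame(scores, index=index, columns=cols), flat[top]


def materialize_kronecker(
    env_matrix: pd.DataFrame, grm, max_cells: int = 5_000_000
) -> np.ndarray:
    """Explicit X = E (x) G for oracle testing, guarded by a size cap."""
    n, m = env_matrix.shape
    q = len(grm.matrix.index)
    cells = (n * q) * (m * q)
    if cells > max_cells:
        raise MemoryError(
            f"materializing X would allocate {cells} cells (> cap {max_cells})"
        )
    return np.kron(
        np.nan_to_num(env_matrix.to_numpy(dtype=float)), grm.matrix.to_numpy()
    )


def build_GEI(
    blues: pd.DataFrame, env_matrix: pd.DataFrame, grm, k: int = 100
) -> ModelInput:
    """Multiplicative (Kronecker) interaction input, factorized SVD to k."""
    _check_envs(blues, env_matrix)
    _check_hybrids(blues, grm)
    scores, _ = kronecker_svd_scores(env_matrix, grm, k=k)
    base = _base_table(blues)
    joined = base.join(scores, on=["Env", "Hybrid"])
    return ModelInput("GEI", _grm_label(grm), joined, svd_components=scores.shape[1])


def _grm_label(grm) -> str:
    return {"additive": "A", "dominance": "D"}.get(grm.kind, grm.kind)


def build_model_input(
    token: str,
    blues: pd.DataFrame,
    env_matrix: pd.DataFrame | None,
    grms: dict | None,
    k: int = 100,
) -> ModelInput:
    """Dispatch on a model token: E, G(A), G(D), G(A)+E, G(D)+E, G(A)EI, G(D)EI."""
    token = token.strip()
    if token == "E":
        return build_E(blues, env_matrix)
    import re

    mt = re.fullmatch(r"G\((A|D)\)(\+E|EI)?", token)
    if not mt:
        raise ValueError(f"unknown model token {token!r}")
    grm = (grms or {}).get(mt.group(1))
    if grm is None:
        raise ValueError(f"no {mt.group(1)} relationship matrix supplied for {token}")
    if mt.group(2) is None:
        return build_G(blues, grm, k=k)
    if mt.group(2) == "+E":
        return build_GplusE(blues, env_matrix, grm, k=k)
    return build_GEI(blues, env_matrix, grm, k=k)
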