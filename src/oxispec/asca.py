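"""ANOVA-simultaneous component analysis (ASCA) for balanced factorial spectra.

The centered data matrix is partitioned additively by the fixed-effects model

    X = mu + X_time + X_temp + X_mat + X_time:temp + X_temp:mat + X_mat:time + E

where each main-effect matrix holds the level mean deviations and each two-way
interaction holds cell-mean deviations after removing the main effects.  In a
balanced, complete design the seven terms are mutually orthogonal, so their
sums of squares add up to the total centered sum of squares; each effect is
then summarised by PCA of its effect matrix (SCA), with residual rows
projected onto the same loadings ("spider" / augmented scores).  Effect
significance is assessed by permuting the design rows against the spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PreprocessedSpectra

__all__ = [
    "EFFECT_NAMES",
    "EffectDecomposition",
    "ScaResult",
    "PermutationResult",
    "decompose",
    "effect_percentages",
    "sca",
    "permutation_test",
    "effects_table",
]

#: Spec factor aliases -> design-table columns.
FACTOR_COLUMNS = {"time": "time", "temp": "temperature", "mat": "material"}

MAIN_EFFECTS = ("time", "temp", "mat")
INTERACTIONS = (("time", "temp"), ("temp", "mat"), ("mat", "time"))
EFFECT_NAMES = ("time", "temp", "mat", "time:temp", "temp:mat", "mat:time")


class UnbalancedDesignError(ValueError):
    """The design is not a complete balanced crossing; the estimators would be biased."""


class ZeroEffectError(ValueError):
    """An all-zero effect matrix admits no component model."""


@dataclass
class EffectDecomposition:
    """Additive partition of a centered spectra matrix by the factorial design."""

    mu: np.ndarray                    # grand-mean spectrum of the input
    effects: dict                     # name -> (n, p) effect matrix
    residual: np.ndarray              # E
    ssq: dict                         # name (incl. "residual") -> sum of squares
    total_ssq: float                  # ||X - mu||^2

    def reconstruct(self) -> np.ndarray:
        """mu + sum of effects + residual; equals the input matrix."""
        out = np.broadcast_to(self.mu, self.residual.shape).copy()
        for m in self.effects.values():
            out += m
        out += self.residual
        return out


@dataclass
class ScaResult:
    """PCA summary of one effect matrix."""

    effect_name: str
    loadings: np.ndarray              # (k, p), orthonormal rows
    scores: np.ndarray                # (n, k), effect rows on the loadings
    spider_scores: np.ndarray         # (n, k), (effect + residual) rows projected
    variance_fraction: np.ndarray     # (k,), sums to 1 over retained components
    n_components: int


@dataclass
class PermutationResult:
    """Empirical significance of one effect under design-row permutation."""

    effect_name: str
    observed_ssq: float
    permuted_ssq: np.ndarray
    p_value: float
    B: int
    seed: int


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, PreprocessedSpectra):
        return X.values
    return np.asarray(X, float)


def _check_balanced(design: pd.DataFrame, n_rows: int) -> None:
    cols = list(FACTOR_COLUMNS.values())
    if len(design) != n_rows:
        raise ValueError(f"design has {len(design)} rows but X has {n_rows}")
    counts = design.groupby(cols, observed=True).size()
    n_cells = int(np.prod([design[c].nunique() for c in cols]))
    if len(counts) != n_cells or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "design must be a complete balanced crossing of time x temperature x material"
        )


def _level_means(Xc: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-level mean rows of Xc, (n_levels, p)."""
    sums = np.zeros((n_levels, Xc.shape[1]))
    np.add.at(sums, codes, Xc)
    counts = np.bincount(codes, minlength=n_levels)[:, None].astype(float)
    return sums / counts


def decompose(X, design: pd.DataFrame) -> EffectDecomposition:
    """Partition X into grand mean, six effect matrices and a residual.

    Rows of ``X`` must be aligned with rows of ``design``.  Main-effect rows
    are level-mean deviations from the grand mean; interaction rows are cell
    means minus both level means plus the grand mean; the residual absorbs
    the three-way interaction and replicate error.  Requires a complete
    balanced design, which makes the partition orthogonal.
    """
    M = _as_matrix(X)
    _check_balanced(design, M.shape[0])

    mu = M.mean(axis=0)
    Xc = M - mu

    codes = {}
    n_levels = {}
    for name, col in FACTOR_COLUMNS.items():
        c, levels = pd.factorize(design[col], sort=True)
        codes[name] = c
        n_levels[name] = len(levels)

    effects: dict[str, np.ndarray] = {}
    for name in MAIN_EFFECTS:
        means = _level_means(Xc, codes[name], n_levels[name])
        effects[name] = means[codes[name]]

    for a, b in INTERACTIONS:
        joint = codes[a] * n_levels[b] + codes[b]
        cell_means = _level_means(Xc, joint, n_levels[a] * n_levels[b])
        effects[f"{a}:{b}"] = cell_means[joint] - effects[a] - effects[b]

    residual = Xc - sum(effects.values())
    ssq = {name: float(np.sum(m * m)) for name, m in effects.items()}
    ssq["residual"] = float(np.sum(residual * residual))
    return EffectDecomposition(
        mu=mu, effects=effects, residual=residual, ssq=ssq,
        total_ssq=float(np.sum(Xc * Xc)),
    )


def effect_percentages(d: EffectDecomposition) -> dict:
    """Each term's sum of squares as a percent of the total centered SSQ."""
    if d.total_ssq <= 0:
        raise ZeroDivisionError("total centered sum of squares is zero; percentages undefined")
    return {name: 100.0 * s / d.total_ssq for name, s in d.ssq.items()}


def sca(
    effect_matrix: np.ndarray,
    residual: np.ndarray,
    effect_name: str = "",
    rank_tol: float = 1e-10,
) -> ScaResult:
    """Simultaneous component analysis of one effect matrix.

    SVD of the effect matrix; components retained at numerical rank
    (singular value > ``rank_tol`` x largest).  Spider scores project the
    residual-augmented rows onto the retained loadings, showing within-level
    dispersion around each level's effect score.
    """
    E = np.asarray(effect_matrix, float)
    if not np.any(E):
        raise ZeroEffectError(f"effect matrix {effect_name!r} is identically zero")
    U, s, Vt = np.linalg.svd(E, full_matrices=False)
    k = int(np.sum(s > rank_tol * s[0]))
    loadings = Vt[:k]
    scores = U[:, :k] * s[:k]
    spider = (E + np.asarray(residual, float)) @ loadings.T
    var = s[:k] ** 2
    return ScaResult(
        effect_name=effect_name,
        loadings=loadings,
        scores=scores,
        spider_scores=spider,
        variance_fraction=var / var.sum(),
        n_components=k,
    )


def _effect_basis(design: pd.DataFrame, effect_name: str) -> np.ndarray:
    """Orthonormal basis C (n, k) of the effect's projection subspace.

    For any row permutation pi, the effect sum of squares of X with design
    rows permuted equals ||C[pi]^T Xc||_F^2, which makes the permutation
    test a single small matmul per draw.
    """
    n = len(design)
    one = np.full((n, 1), 1.0 / np.sqrt(n))
    P1 = one @ one.T

    def averaging(labels: np.ndarray) -> np.ndarray:
        codes, _ = pd.factorize(labels)
        Z = np.zeros((n, codes.max() + 1))
        Z[np.arange(n), codes] = 1.0
        return Z @ np.diag(1.0 / Z.sum(axis=0)) @ Z.T

    cols = FACTOR_COLUMNS
    if effect_name in MAIN_EFFECTS:
        H = averaging(design[cols[effect_name]].to_numpy()) - P1
    else:
        a, b = effect_name.split(":")
        la = design[cols[a]].astype(str).to_numpy()
        lb = design[cols[b]].astype(str).to_numpy()
        joint = np.char.add(np.char.add(la, "|"), lb)
        H = averaging(joint) - averaging(la) - averaging(lb) + P1

    w, V = np.linalg.eigh(H)
    return V[:, w > 0.5]  # projector eigenvalues are 0/1


def permutation_test(
    X, design: pd.DataFrame, effect_name: str, B: int = 5000, seed: int = 0
) -> PermutationResult:
    """Permutation significance of one effect's sum of squares.

    Each draw shuffles the whole design-row assignment against the spectra
    (the y-block is permuted), recomputes the decomposition and records the
    effect's SSQ.  p = max(#{permuted >= observed}, 1) / B, so the smallest
    attainable p is 1/B (0.0002 at B = 5000); ties count against the effect.
    """
    if effect_name not in EFFECT_NAMES:
        raise ValueError(f"unknown effect {effect_name!r}; expected one of {EFFECT_NAMES}")
    if B < 1:
        raise ValueError("B must be >= 1")
    M = _as_matrix(X)
    _check_balanced(design, M.shape[0])
    Xc = M - M.mean(axis=0)

    C = _effect_basis(design, effect_name)
    observed = float(np.sum((C.T @ Xc) ** 2))

    rng = np.random.default_rng(seed)
    n = M.shape[0]
    permuted = np.empty(B)
    for b in range(B):
        pi = rng.permutation(n)
        permuted[b] = np.sum((C[pi].T @ Xc) ** 2)

    count = int(np.sum(permuted >= observed))
    return PermutationResult(
        effect_name=effect_name,
        observed_ssq=observed,
        permuted_ssq=permuted,
        p_value=max(count, 1) / B,
        B=B,
        seed=seed,
    )


def effects_table(
    X, design: pd.DataFrame, B: int = 5000, seed: int = 0
) -> pd.DataFrame:
    """Summary table per effect: retained PCs, effect %, permutation p-value."""
    d = decompose(X, design)
    pct = effect_percentages(d)
    rows = []
    for i, name in enumerate(EFFECT_NAMES):
        res = sca(d.effects[name], d.residual, name)
        perm = permutation_test(X, design, name, B=B, seed=seed + i)
        rows.append(
            {"effect": name, "pcs": res.n_components,
             "effect_pct": pct[name], "p_value": perm.p_value}
        )
    rows.append({"effect": "residual", "pcs": None,
                 "effect_pct": pct["residual"], "p_value": None})
    return pd.DataFrame(rows)
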