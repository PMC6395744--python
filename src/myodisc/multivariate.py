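"""Full-SVD PCA, pairwise Fisher LDA on PC scores, and discriminant gene ranking.

The dimensionality-reduction core of the analysis: the standardized 30 x 27
expression matrix is decomposed into all 27 eigenpairs by SVD; for each of the
three group contrasts a binary Fisher discriminant is fit in closed form on
the first three PC scores of that contrast's samples; the per-gene
discriminant weight is the dot product of the gene's first-three PC loadings
with the LD coefficient vector, and genes are ranked by |weight| ascending so
the most discriminant genes sit at the bottom of each list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import OutlierReport, PreprocessConfig, StandardizedMatrix, preprocess
from .simulate import ExpressionDataset

__all__ = [
    "PCAModel",
    "ContrastSpec",
    "DEFAULT_CONTRASTS",
    "LDAModel",
    "DiscriminantGeneList",
    "PipelineResult",
    "fit_pca",
    "fit_lda_binary",
    "compute_discriminant_weights",
    "rank_genes",
    "run_pcalda",
]


@dataclass
class PCAModel:
    """Eigenpairs of the standardized expression matrix.

    ``loadings`` has orthonormal columns (genes x components) with the sign
    convention that each column's largest-magnitude entry is positive;
    ``scores`` = z @ loadings; ``explained_variance`` are the (n-1)-denominator
    eigenvalues in non-increasing order.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int


@dataclass(frozen=True)
class ContrastSpec:
    """A two-class group contrast; class_b is the more-affected side."""

    name: str
    class_a: frozenset[str]
    class_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.class_a & self.class_b:
            raise ValueError(f"contrast {self.name!r}: classes overlap")

    @property
    def groups(self) -> frozenset[str]:
        return self.class_a | self.class_b


#: The three contrasts of the study design: ubiquitous SOD1(G93A) vs its
#: wild types, muscle-restricted MLC/SOD1(G93A) vs its wild type, and the
#: two transgenic models against each other.
DEFAULT_CONTRASTS: tuple[ContrastSpec, ...] = (
    ContrastSpec(
        "SOD1_vs_WT",
        class_a=frozenset({"WT_C57_90", "WT_C57_130"}),
        class_b=frozenset({"SOD1_90", "SOD1_130"}),
    ),
    ContrastSpec("MLC_vs_WT", class_a=frozenset({"WT_FVB"}), class_b=frozenset({"MLC"})),
    ContrastSpec(
        "MLC_vs_SOD1",
        class_a=frozenset({"MLC"}),
        class_b=frozenset({"SOD1_90", "SOD1_130"}),
    ),
)


@dataclass
class LDAModel:
    """Closed-form binary Fisher discriminant over the first PC scores."""

    contrast: ContrastSpec
    ld_coefficients: np.ndarray  # unit-norm vector over PC1..PCk
    ld_scores: pd.Series  # per sample of the contrast
    class_mean_a: float
    class_mean_b: float


@dataclass
class DiscriminantGeneList:
    """Per-gene PCA-LDA weights for one contrast, ranked by |weight|.

    ``table`` is sorted ascending in abs_weight (ties keep input gene order)
    with rank 1..n, so the most discriminant genes appear at the bottom.
    """

    contrast_name: str
    table: pd.DataFrame  # columns: gene, weight, abs_weight, rank

    @property
    def genes_bottom(self) -> list[str]:
        """Gene names from least to most discriminant."""
        return list(self.table["gene"])

    def top(self, k: int) -> list[str]:
        """The k most discriminant genes, most discriminant first."""
        return list(self.table["gene"].iloc[::-1].iloc[:k])


@dataclass
class PipelineResult:
    pca: PCAModel
    ldas: dict[str, LDAModel]
    gene_lists: dict[str, DiscriminantGeneList]
    standardized: StandardizedMatrix
    outlier_report: OutlierReport
    contrasts: tuple[ContrastSpec, ...] = DEFAULT_CONTRASTS


def fit_pca(z, n_components: int | None = None) -> PCAModel:
    """All requested eigenpairs of the covariance of ``z`` via full SVD.

    ``z`` may be a StandardizedMatrix or a samples x genes DataFrame with no
    empty cells.  Column signs are fixed so the largest-magnitude entry of
    each loading column is positive; explained-variance ratios divide each
    eigenvalue by the total variance of ``z``.
    """
    zdf = z.z if isinstance(z, StandardizedMatrix) else pd.DataFrame(z)
    if zdf.isna().any().any():
        raise ValueError("fit_pca requires a matrix with no empty cells")
    n, p = zdf.shape
    max_comp = min(n, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )

    x = zdf.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = (s * s) / (n - 1)
    total_var = float(x.var(axis=0, ddof=1).sum())
    loadings = vt.T[:, :n_components]

    # SVD leaves each component's sign arbitrary; pin it.
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    loadings_df = pd.DataFrame(loadings, index=zdf.columns, columns=comp_names)
    scores = pd.DataFrame(x @ loadings, index=zdf.index, columns=comp_names)
    ev = eigvals[:n_components]
    return PCAModel(
        loadings=loadings_df,
        scores=scores,
        explained_variance=ev,
        explained_variance_ratio=ev / total_var,
        n_components=n_components,
    )


def fit_lda_binary(
    scores: pd.DataFrame,
    labels: pd.Series,
    contrast: ContrastSpec,
    ridge: bool = False,
) -> LDAModel:
    """Fisher discriminant direction w ~ Sw^-1 (mu_b - mu_a), unit norm.

    ``scores`` holds the PC scores of the contrast's samples only; ``labels``
    their group names.  Sw is the pooled within-class scatter matrix.  The
    sign convention puts the class_b (more affected) mean above the class_a
    mean on the LD axis.  A singular Sw raises unless ``ridge`` is set, in
    which case eps = 1e-8 * trace(Sw) is added to the diagonal.
    """
    in_a = labels.isin(contrast.class_a).to_numpy()
    in_b = labels.isin(contrast.class_b).to_numpy()
    if not (in_a | in_b).all():
        stray = sorted(set(labels[~(in_a | in_b)]))
        raise ValueError(f"contrast {contrast.name!r}: unexpected groups {stray}")
    a = scores.to_numpy(dtype=float)[in_a]
    b = scores.to_numpy(dtype=float)[in_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"contrast {contrast.name!r}: each class needs >= 2 samples "
            f"(got {len(a)} vs {len(b)})"
        )

    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    delta = mu_b - mu_a
    if np.linalg.norm(delta) == 0.0:
        raise ValueError(
            f"contrast {contrast.name!r}: identical class means, no discriminating direction"
        )
    ca = a - mu_a
    cb = b - mu_b
    sw = ca.T @ ca + cb.T @ cb
    if ridge:
        sw = sw + 1e-8 * np.trace(sw) * np.eye(sw.shape[0])
    try:
        w = np.linalg.solve(sw, delta)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"contrast {contrast.name!r}: singular within-class scatter; "
            "retry with ridge=True (eps = 1e-8 * trace)"
        ) from err
    w = w / np.linalg.norm(w)

    ld = scores.to_numpy(dtype=float) @ w
    mean_a = float(ld[in_a].mean())
    mean_b = float(ld[in_b].mean())
    if mean_b < mean_a:
        w, ld, mean_a, mean_b = -w, -ld, -mean_a, -mean_b
    return LDAModel(
        contrast=contrast,
        ld_coefficients=w,
        ld_scores=pd.Series(ld, index=scores.index, name=f"LD_{contrast.name}"),
        class_mean_a=mean_a,
        class_mean_b=mean_b,
    )


def compute_discriminant_weights(
    loadings: pd.DataFrame, ld_coefficients: np.ndarray, contrast_name: str = ""
) -> pd.Series:
    """Per-gene weight = loadings (genes x k) @ LD coefficients (k,)."""
    coef = np.asarray(ld_coefficients, dtype=float).ravel()
    if loadings.shape[1] != coef.size:
        raise ValueError(
            f"dimension mismatch: loadings have {loadings.shape[1]} components, "
            f"LD coefficients have {coef.size}"
        )
    return pd.Series(
        loadings.to_numpy(dtype=float) @ coef,
        index=loadings.index,
        name=contrast_name or "weight",
    )


def rank_genes(weights: pd.Series, contrast_name: str = "") -> DiscriminantGeneList:
    """Stable ascending sort on |weight|; rank n is the most discriminant."""
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    order = np.argsort(np.abs(w), kind="stable")
    table = pd.DataFrame(
        {
            "gene": np.asarray(weights.index)[order],
            "weight": w[order],
            "abs_weight": np.abs(w)[order],
            "rank": np.arange(1, w.size + 1),
        }
    ).reset_index(drop=True)
    return DiscriminantGeneList(contrast_name or str(weights.name), table)


def run_pcalda(
    ds: ExpressionDataset,
    preprocess_cfg: PreprocessConfig | None = None,
    contrasts: tuple[ContrastSpec, ...] = DEFAULT_CONTRASTS,
    n_discriminant_pcs: int = 3,
) -> PipelineResult:
    """The full pipeline: preprocess, PCA, one LDA + gene ranking per contrast.

    PC scores come from the single PCA over all samples; each contrast's LDA
    is then fit only on that contrast's samples, restricted to the first
    ``n_discriminant_pcs`` PC scores, and the gene weights multiply the
    matching loadings block by the LD coefficient vector.
    """
    present = set(ds.groups)
    for contrast in contrasts:
        miss = contrast.groups - present
        if miss:
            raise ValueError(
                f"[pcalda] dataset lacks groups {sorted(miss)} required by "
                f"contrast {contrast.name!r}"
            )

    try:
        standardized, report = preprocess(ds, preprocess_cfg)
    except Exception as err:
        raise RuntimeError(f"[preprocess] {err}") from err
    try:
        pca = fit_pca(standardized)
    except Exception as err:
        raise RuntimeError(f"[pca] {err}") from err

    k = min(n_discriminant_pcs, pca.n_components)
    pcs = pca.scores.columns[:k]
    ldas: dict[str, LDAModel] = {}
    gene_lists: dict[str, DiscriminantGeneList] = {}
    for contrast in contrasts:
        samples = ds.samples_in(contrast.groups)
        try:
            lda = fit_lda_binary(
                pca.scores.loc[samples, pcs], ds.groups.loc[samples], contrast
            )
            weights = compute_discriminant_weights(
                pca.loadings[pcs], lda.ld_coefficients, contrast.name
            )
            gene_lists[contrast.name] = rank_genes(weights, contrast.name)
        except Exception as err:
            raise RuntimeError(f"[lda:{contrast.name}] {err}") from err
        ldas[contrast.name] = lda

    return PipelineResult(
        pca=pca,
        ldas=ldas,
        gene_lists=gene_lists,
        standardized=standardized,
        outlier_report=report,
        contrasts=contrasts,
    )
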