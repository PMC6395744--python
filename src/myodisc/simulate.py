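"""Seeded synthetic qPCR expression datasets for the six-group ALS muscle design.

The generator emulates a 30-muscle x 27-gene panel of housekeeping-normalized
expression ratios: two ubiquitous-SOD1(G93A) time points (90 and 130 days) with
their age/strain-matched C57BL6J wild types, plus the muscle-restricted
MLC/SOD1(G93A) model with its FVB/NJ wild type.  Group effects are encoded as
relative fold changes FC = transgenic/control - 1 applied to per-gene baseline
means, with multiplicative log-normal noise, and optional injected gross
outliers and missing cells so the outlier-handling front end of the analysis
pipeline can be exercised against a known ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupLabel",
    "GROUPS",
    "GROUP_ORDER",
    "DEFAULT_GENES",
    "DEFAULT_FC_MAP",
    "OutlierSpec",
    "MissingSpec",
    "SimulationConfig",
    "ExpressionDataset",
    "AnomalyLedger",
    "generate_dataset",
    "inject_anomalies",
]


@dataclass(frozen=True)
class GroupLabel:
    """One experimental group: strain, genotype and age at sacrifice."""

    name: str
    strain: str
    genotype: str  # "WT" or "TG"
    age_days: int

    @property
    def is_transgenic(self) -> bool:
        return self.genotype == "TG"


#: The six experimental groups, in canonical row order.
GROUPS: dict[str, GroupLabel] = {
    "WT_C57_90": GroupLabel("WT_C57_90", "C57BL6J", "WT", 90),
    "WT_C57_130": GroupLabel("WT_C57_130", "C57BL6J", "WT", 130),
    "SOD1_90": GroupLabel("SOD1_90", "C57BL6J", "TG", 90),
    "SOD1_130": GroupLabel("SOD1_130", "C57BL6J", "TG", 130),
    "WT_FVB": GroupLabel("WT_FVB", "FVB/NJ", "WT", 140),
    "MLC": GroupLabel("MLC", "FVB/NJ", "TG", 140),
}

GROUP_ORDER: tuple[str, ...] = tuple(GROUPS)

#: The 27-gene panel (ion channels, pumps, kinases, myokines, fiber-type
#: markers), in the order the expression matrix columns are laid out.
DEFAULT_GENES: tuple[str, ...] = (
    "ClC1", "PKC_theta", "PKC_alpha", "Ryr1", "Serca1", "Serca2", "CN",
    "Bk", "Kir6.2", "Sur1", "Sur2a", "Sur2b", "Nav1.4", "Nmdar1", "Ampar2",
    "Murf1", "Irisin", "Notch1", "TauT", "Ampk", "Ngf", "Mstn", "Achr1",
    "Mhc2b", "Mhc2x", "Mhc2a", "Mhc1",
)

# Default per-group fold changes.  Signs follow the reported transcriptional
# changes in each transgenic group (wild types are 0 everywhere); magnitudes
# are tiered in {0.3, 0.5, 0.8} with the MLC contrast's top discriminant
# markers (Ampar2, PKC_theta, Irisin) on the largest tier.  The Irisin and
# PKC_theta effects shared with SOD1_90 sit on the smallest tier so their
# MLC-specific signal is not absorbed into the dominant SOD1 variance axis.
DEFAULT_FC_MAP: dict[str, dict[str, float]] = {
    "WT_C57_90": {},
    "WT_C57_130": {},
    "SOD1_90": {
        "ClC1": -0.8, "Serca1": -0.8, "Nav1.4": -0.8, "Sur2b": -0.5,
        "Mstn": -0.5, "Notch1": -0.5, "Irisin": -0.3,
        "PKC_theta": 0.3, "PKC_alpha": 0.5, "Serca2": 0.5, "CN": 0.5,
        "Sur1": 0.5, "TauT": 0.5, "Achr1": 0.5,
        "Mhc2b": -0.3, "Mhc2a": 0.3, "Mhc1": 0.3,
    },
    "SOD1_130": {
        "ClC1": -0.8, "Serca1": -0.8, "Nav1.4": -0.8,
        "Bk": -0.5, "Kir6.2": -0.5, "Sur2a": -0.5, "Sur2b": -0.5,
        "Ampk": -0.5, "Ryr1": -0.5, "Notch1": -0.5, "Ngf": -0.5, "Mstn": -0.5,
        "Serca2": 0.5, "Sur1": 0.5, "Achr1": 0.5,
        "Mhc2b": -0.5, "Mhc2a": 0.5, "Mhc1": 0.5,
    },
    "WT_FVB": {},
    "MLC": {
        "Irisin": -0.8, "Ampar2": 0.8, "PKC_theta": 0.8, "Mstn": -0.3,
    },
}


@dataclass(frozen=True)
class OutlierSpec:
    """How many cells to corrupt and by which multiplicative factor."""

    count: int = 2
    magnitude: float = 10.0


@dataclass(frozen=True)
class MissingSpec:
    """How many cells to blank out."""

    count: int = 0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design.

    ``fc_map`` maps group name -> {gene -> fold change}; genes absent from a
    group's entry default to 0 (no effect).  ``baseline_mean`` may be a scalar
    applied to every gene or a per-gene mapping; expression ratios to the
    housekeeping gene default to 1.0.  Noise is multiplicative log-normal with
    median 1 and coefficient of variation ``noise_cv``.
    """

    n_per_group: int = 5
    genes: tuple[str, ...] = DEFAULT_GENES
    baseline_mean: float | dict[str, float] = 1.0
    fc_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_FC_MAP.items()}
    )
    noise_cv: float = 0.12
    outlier_spec: OutlierSpec = OutlierSpec()
    missing_spec: MissingSpec = MissingSpec()
    seed: int = 0

    def baseline_of(self, gene: str) -> float:
        if isinstance(self.baseline_mean, dict):
            return float(self.baseline_mean[gene])
        return float(self.baseline_mean)

    def fc_of(self, group: str, gene: str) -> float:
        return float(self.fc_map.get(group, {}).get(gene, 0.0))

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(
                "n_per_group must be >= 2 (LDA needs within-class scatter), "
                f"got {self.n_per_group}"
            )
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("gene names must be unique")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        for group in self.fc_map:
            if group not in GROUPS:
                raise ValueError(f"unknown group in fc_map: {group!r}")
        for group, genes in self.fc_map.items():
            if GROUPS[group].genotype == "WT":
                bad = {g: fc for g, fc in genes.items() if fc != 0.0}
                if bad:
                    raise ValueError(f"wild-type group {group} must have FC = 0, got {bad}")
            for gene, fc in genes.items():
                if gene not in self.genes:
                    raise ValueError(f"fc_map names unknown gene {gene!r}")
                if fc <= -1.0:
                    raise ValueError(
                        f"FC must be > -1 (expression stays positive); "
                        f"fc_map[{group!r}][{gene!r}] = {fc}"
                    )
        for gene in self.genes:
            if self.baseline_of(gene) <= 0:
                raise ValueError(f"baseline_mean for {gene!r} must be > 0")


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with per-sample group labels.

    ``values`` is indexed by sample id with one column per gene; ``groups``
    maps sample id -> group name.  NaN entries represent empty (missing)
    cells and are only expected between anomaly injection and imputation.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ValueError("values and groups must share the same sample index")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def samples_in(self, group_names) -> list[str]:
        wanted = {group_names} if isinstance(group_names, str) else set(group_names)
        return [s for s, g in self.groups.items() if g in wanted]

    def metadata(self) -> pd.DataFrame:
        """Sample metadata table (sample_id, group, strain, genotype, age_days)."""
        rows = []
        for sid, gname in self.groups.items():
            g = GROUPS[gname]
            rows.append(
                {"sample_id": sid, "group": g.name, "strain": g.strain,
                 "genotype": g.genotype, "age_days": g.age_days}
            )
        return pd.DataFrame(rows).set_index("sample_id")

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.values.copy(), self.groups.copy())


@dataclass(frozen=True)
class AnomalyLedger:
    """Ground truth of the injected anomalies, for recovery tests."""

    outliers: tuple[tuple[str, str], ...]  # (sample_id, gene)
    missing: tuple[tuple[str, str], ...]
    magnitude: float


def _lognormal_sigma(cv: float) -> float:
    # sigma of the underlying normal so that exp(N(0, sigma^2)) has the
    # requested coefficient of variation (and median 1).
    return math.sqrt(math.log(1.0 + cv * cv))


def generate_dataset(config: SimulationConfig) -> ExpressionDataset:
    """Draw one seeded dataset from the configured study design.

    Each cell is ``baseline(g) * (1 + FC(group, g)) * eps`` with eps
    log-normal, median 1, CV = ``noise_cv``.  Rows are laid out group by
    group in canonical order; the default design gives 6 x 5 = 30 rows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sigma = _lognormal_sigma(config.noise_cv)
    genes = list(config.genes)
    blocks, sample_ids, labels = [], [], []
    for gname in GROUP_ORDER:
        mu = np.array(
            [config.baseline_of(g) * (1.0 + config.fc_of(gname, g)) for g in genes]
        )
        shape = (config.n_per_group, len(genes))
        eps = np.exp(rng.normal(0.0, sigma, shape)) if sigma > 0 else np.ones(shape)
        blocks.append(mu * eps)
        sample_ids.extend(f"{gname}_{i + 1}" for i in range(config.n_per_group))
        labels.extend([gname] * config.n_per_group)
    values = pd.DataFrame(np.vstack(blocks), index=sample_ids, columns=genes)
    groups = pd.Series(labels, index=sample_ids, name="group")
    return ExpressionDataset(values, groups)


def inject_anomalies(
    ds: ExpressionDataset,
    outlier_spec: OutlierSpec,
    missing_spec: MissingSpec,
    seed: int,
) -> tuple[ExpressionDataset, AnomalyLedger]:
    """Corrupt a copy of ``ds`` with gross outliers and empty cells.

    Exactly ``outlier_spec.count`` cells are multiplied by
    ``outlier_spec.magnitude`` and exactly ``missing_spec.count`` distinct
    cells are blanked (NaN); the missing draw is taken from the cells not
    already chosen as outliers, so an overlap is resolved deterministically
    by the seed.  Returns the corrupted dataset and the ground-truth ledger.
    """
    n_cells = ds.n_samples * ds.n_genes
    if outlier_spec.count + missing_spec.count > n_cells:
        raise ValueError("requested anomaly count exceeds number of cells")
    if outlier_spec.count == 0 and missing_spec.count == 0:
        return ds.copy(), AnomalyLedger((), (), outlier_spec.magnitude)

    rng = np.random.default_rng(seed)
    flat_out = rng.choice(n_cells, size=outlier_spec.count, replace=False)
    remaining = np.setdiff1d(np.arange(n_cells), flat_out)
    flat_miss = rng.choice(remaining, size=missing_spec.count, replace=False)

    out = ds.copy()
    mat = out.values.to_numpy()

    def cell(flat: int) -> tuple[int, int]:
        return divmod(int(flat), ds.n_genes)

    outliers, missing = [], []
    for f in flat_out:
        r, c = cell(f)
        mat[r, c] *= outlier_spec.magnitude
        outliers.append((out.sample_ids[r], out.gene_names[c]))
    for f in flat_miss:
        r, c = cell(f)
        mat[r, c] = np.nan
        missing.append((out.sample_ids[r], out.gene_names[c]))
    out.values.iloc[:, :] = mat
    return out, AnomalyLedger(tuple(outliers), tuple(missing), outlier_spec.magnitude)


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON/YAML-serializable form of a SimulationConfig."""
    d = dataclasses.asdict(config)
    d["genes"] = list(config.genes)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "genes" in d:
        d["genes"] = tuple(d["genes"])
    if isinstance(d.get("outlier_spec"), dict):
        d["outlier_spec"] = OutlierSpec(**d["outlier_spec"])
    if isinstance(d.get("missing_spec"), dict):
        d["missing_spec"] = MissingSpec(**d["missing_spec"])
    return SimulationConfig(**d)
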