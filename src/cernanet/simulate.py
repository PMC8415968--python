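"""Synthetic multi-layer expression data with planted sponge triplets.

The generator emulates a two-group (Lean control vs MetS case) EV
transcriptomics design with three RNA layers.  Each planted triplet
(lncRNA, miRNA, mRNA) is driven by one latent per-sample miRNA activity
``a``: the miRNA's log-expression rises with ``a`` while its mRNA target
and lncRNA sponge fall with ``a`` (coupling strengths ``beta_mrna`` /
``beta_lncrna``).  Shifting the mean of ``a`` upward in the case group
therefore produces, from a single mechanism, the triplet signature a
ceRNA screen is built to detect: miRNA up, mRNA and lncRNA down, lncRNA
and mRNA positively correlated, each negatively correlated with the miRNA.

Log-expression is mapped to counts by scaling every sample (within each
RNA layer) to an expected ``library_size`` and Poisson sampling.  All
randomness flows from one ``numpy`` generator, so identical parameters
(including the seed) give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import (
    GROUP_CASE,
    GROUP_CONTROL,
    ExpressionMatrix,
    InteractionTable,
    write_expression,
    write_interactions,
    write_metadata,
)


@dataclass(frozen=True)
class SimulationParams:
    """Study-design and signal parameters of the generator.

    Defaults mirror a small circulating-EV case/control study: five
    samples per group, three RNA layers of realistic relative sizes, and
    a strong planted sponge signal (case-group miRNA activity shifted by
    ``group_shift`` on the natural-log scale).
    """

    n_per_group: int = 5
    n_lncrna: int = 2000
    n_mirna: int = 1500
    n_mrna: int = 8000
    n_triplets: int = 20
    beta_mrna: float = 1.5
    beta_lncrna: float = 1.5
    group_shift: float = 2.0
    noise_sd: float = 0.3
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    library_size: float = 1_000_000.0
    decoy_interactions: int = 200
    seed: int = 0

    def validate(self) -> None:
        for fld in ("n_per_group", "n_lncrna", "n_mirna", "n_mrna"):
            if getattr(self, fld) < 1:
                raise ParameterError(f"{fld} must be >= 1")
        if self.n_triplets < 0:
            raise ParameterError("n_triplets must be >= 0")
        if self.n_triplets > min(self.n_lncrna, self.n_mirna, self.n_mrna):
            raise ParameterError(
                "n_triplets exceeds the smallest per-kind feature count"
            )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.baseline_log_sd < 0:
            raise ParameterError("baseline_log_sd must be >= 0")
        if self.library_size <= 0:
            raise ParameterError("library_size must be > 0")
        if self.decoy_interactions < 0:
            raise ParameterError("decoy_interactions must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset, for parameter-recovery scoring."""

    planted_triplets: list[tuple[str, str, str]]
    planted_de: dict[str, list[tuple[str, str]]]  # kind -> [(feature_id, direction)]
    params: SimulationParams


@dataclass(frozen=True)
class SyntheticDataset:
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    mir_mrna: InteractionTable
    mir_lncrna: InteractionTable
    truth: SyntheticTruth

    @property
    def matrices(self) -> dict[str, ExpressionMatrix]:
        return {"lncRNA": self.lncrna, "miRNA": self.mirna, "mRNA": self.mrna}


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _log_expression(
    rng: np.random.Generator,
    n_features: int,
    n_samples: int,
    params: SimulationParams,
    planted_effect: np.ndarray | None,
) -> np.ndarray:
    """baseline + (planted coupling rows) + residual noise, natural-log scale."""
    baseline = rng.normal(params.baseline_log_mean, params.baseline_log_sd, n_features)
    logx = np.tile(baseline[:, None], (1, n_samples))
    if planted_effect is not None:
        logx[: planted_effect.shape[0]] += planted_effect
    logx += rng.normal(0.0, params.noise_sd, (n_features, n_samples))
    return logx


def _to_counts(rng: np.random.Generator, logx: np.ndarray, library_size: float) -> np.ndarray:
    expr = np.exp(logx)
    lam = expr / expr.sum(axis=0, keepdims=True) * library_size
    return rng.poisson(lam)


def generate_log_expression(
    params: SimulationParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Latent log-expression for the three layers (no count sampling).

    Planted features occupy the first ``n_triplets`` rows of each layer;
    triplet *i* couples row *i* of each layer through one latent activity.
    """
    n_samples = 2 * params.n_per_group
    mu = np.zeros(n_samples)
    mu[params.n_per_group:] = params.group_shift  # case samples last
    a = rng.normal(0.0, 1.0, (params.n_triplets, n_samples)) + mu
    return {
        "lncRNA": _log_expression(rng, params.n_lncrna, n_samples, params, -params.beta_lncrna * a),
        "miRNA": _log_expression(rng, params.n_mirna, n_samples, params, a),
        "mRNA": _log_expression(rng, params.n_mrna, n_samples, params, -params.beta_mrna * a),
    }


def _decoy_pairs(
    rng: np.random.Generator,
    mirna_ids: list[str],
    target_ids: list[str],
    planted: set[tuple[str, str]],
    n_decoys: int,
) -> list[tuple[str, str]]:
    """Sample unique non-planted (miRNA, target) pairs without replacement.

    Small pair universes are enumerated outright; large ones use seeded
    rejection sampling to avoid materialising every pair.  Both paths are
    deterministic for a given generator state.
    """
    n_total = len(mirna_ids) * len(target_ids)
    n_available = n_total - len(planted)
    if n_decoys > n_available:
        raise ParameterError(
            "decoy_interactions exceeds the number of available non-planted pairs"
        )
    if n_total <= 50_000 or n_decoys > n_available // 2:
        candidates = [
            (m, t) for m in mirna_ids for t in target_ids if (m, t) not in planted
        ]
        idx = rng.choice(len(candidates), size=n_decoys, replace=False)
        return [candidates[i] for i in sorted(idx)]
    chosen: dict[tuple[str, str], None] = {}
    while len(chosen) < n_decoys:
        need = n_decoys - len(chosen)
        mi = rng.integers(0, len(mirna_ids), size=2 * need)
        ti = rng.integers(0, len(target_ids), size=2 * need)
        for i, j in zip(mi, ti):
            pair = (mirna_ids[i], target_ids[j])
            if pair not in planted and pair not in chosen:
                chosen[pair] = None
                if len(chosen) == n_decoys:
                    break
    return sorted(chosen)


def generate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Generate the three count matrices, interaction tables and ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_samples = 2 * params.n_per_group
    sample_ids = [f"Lean_{i}" for i in range(1, params.n_per_group + 1)] + [
        f"MetS_{i}" for i in range(1, params.n_per_group + 1)
    ]
    groups = pd.Series(
        [GROUP_CONTROL] * params.n_per_group + [GROUP_CASE] * params.n_per_group,
        index=pd.Index(sample_ids, name="sample_id"),
        name="group",
    )
    ids = {
        "lncRNA": _feature_ids("lnc", params.n_lncrna),
        "miRNA": _feature_ids("mir", params.n_mirna),
        "mRNA": _feature_ids("gene", params.n_mrna),
    }

    logx = generate_log_expression(params, rng)
    matrices = {}
    for kind in ("lncRNA", "miRNA", "mRNA"):
        counts = _to_counts(rng, logx[kind], params.library_size)
        matrices[kind] = ExpressionMatrix(
            values=pd.DataFrame(counts, index=ids[kind], columns=sample_ids),
            kind=kind,
            groups=groups,
            scale="counts",
        )

    triplets = [
        (ids["lncRNA"][i], ids["miRNA"][i], ids["mRNA"][i])
        for i in range(params.n_triplets)
    ]
    planted_mrna_pairs = {(m, g) for _l, m, g in triplets}
    planted_lnc_pairs = {(m, l) for l, m, _g in triplets}

    n_decoy_mrna = params.decoy_interactions // 2 + params.decoy_interactions % 2
    n_decoy_lnc = params.decoy_interactions // 2
    decoys_mrna = _decoy_pairs(rng, ids["miRNA"], ids["mRNA"], planted_mrna_pairs, n_decoy_mrna)
    decoys_lnc = _decoy_pairs(rng, ids["miRNA"], ids["lncRNA"], planted_lnc_pairs, n_decoy_lnc)

    def _table(planted: list[tuple[str, str]], decoys: list[tuple[str, str]], kind: str, src: str):
        rows = [(m, t, kind, src) for m, t in planted] + [
            (m, t, kind, "decoy") for m, t in decoys
        ]
        return InteractionTable(
            pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_kind", "source"])
        )

    mir_mrna = _table(sorted(planted_mrna_pairs), decoys_mrna, "mRNA", "planted")
    mir_lncrna = _table(sorted(planted_lnc_pairs), decoys_lnc, "lncRNA", "planted")

    truth = SyntheticTruth(
        planted_triplets=triplets,
        planted_de={
            "miRNA": [(ids["miRNA"][i], "up") for i in range(params.n_triplets)],
            "mRNA": [(ids["mRNA"][i], "down") for i in range(params.n_triplets)],
            "lncRNA": [(ids["lncRNA"][i], "down") for i in range(params.n_triplets)],
        },
        params=params,
    )
    return SyntheticDataset(
        lncrna=matrices["lncRNA"],
        mirna=matrices["miRNA"],
        mrna=matrices["mRNA"],
        mir_mrna=mir_mrna,
        mir_lncrna=mir_lncrna,
        truth=truth,
    )


FIXTURE_FILES = {
    "lncrna": "expression_lncrna.tsv",
    "mirna": "expression_mirna.tsv",
    "mrna": "expression_mrna.tsv",
    "metadata": "samples.tsv",
    "mir_mrna": "interactions_mirna_mrna.tsv",
    "mir_lncrna": "interactions_mirna_lncrna.tsv",
    "truth": "truth_triplets.tsv",
}


def write_fixture(dataset: SyntheticDataset, out_dir: str | Path) -> list[Path]:
    """Write the dataset as a seven-file TSV fixture directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [
        write_expression(dataset.lncrna, out / FIXTURE_FILES["lncrna"]),
        write_expression(dataset.mirna, out / FIXTURE_FILES["mirna"]),
        write_expression(dataset.mrna, out / FIXTURE_FILES["mrna"]),
        write_metadata(dataset.lncrna.groups, out / FIXTURE_FILES["metadata"]),
        write_interactions(dataset.mir_mrna, out / FIXTURE_FILES["mir_mrna"]),
        write_interactions(dataset.mir_lncrna, out / FIXTURE_FILES["mir_lncrna"]),
    ]
    truth_path = out / FIXTURE_FILES["truth"]
    pd.DataFrame(
        dataset.truth.planted_triplets, columns=["lncrna_id", "mirna_id", "mrna_id"]
    ).to_csv(truth_path, sep="\t", index=False, lineterminator="\n")
    paths.append(truth_path)
    return paths


def read_truth(path: str | Path) -> list[tuple[str, str, str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(row) for row in frame[["lncrna_id", "mirna_id", "mrna_id"]].to_numpy()]
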