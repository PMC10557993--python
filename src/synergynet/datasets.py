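"""Synthetic data generators with ground-truth manifests.

Two families of data stand in for what the methods are meant to analyse:

- samples from the reference Bayesian network (``generate_reference_dataset``),
- geriatric-screening-style binary survey tables (``generate_survey``): a few hundred to
  a few thousand subjects by ~37 "sign" and ~14 "disease" columns, with
  skewed background prevalences, planted noisy-copy pairwise links, planted
  XOR synergistic triplets, and OR-gate disease columns.  A matched
  all-independent null table (``generate_null_survey``) supports type-I
  error checks.

Every generator is deterministic given its seed and emits a manifest naming
each planted mechanism, so recovery of the planted structure can be scored
exactly.

Planted XOR inputs draw their prevalences from a near-balanced window
(default U(0.4, 0.6)) rather than the skewed background range: the XOR of
two strongly skewed inputs has a large *pairwise* MI with each input, which
would eject the triple from the low-MI triangle filter and make the planted
synergy undetectable by construction rather than by statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bayesnet import BayesNet, sample_dataframe
from .info import DataMatrix

__all__ = [
    "SurveyGenConfig",
    "GroundTruthManifest",
    "generate_reference_dataset",
    "generate_survey",
    "generate_null_survey",
    "verify_manifest",
]


@dataclass(frozen=True)
class SurveyGenConfig:
    """Shape and mechanism settings for the survey generator.

    Defaults mirror the geriatric screening table the generator emulates:
    587 subjects, 37 binary signs, 14 binarized disease indicators, with
    background prevalences skewed low as in real sign data.
    """

    n_subjects: int = 587
    n_signs: int = 37
    n_diseases: int = 14
    n_planted_triplets: int = 5
    n_planted_pairs: int = 3
    flip_noise: float = 0.05
    prevalence_range: tuple[float, float] = (0.05, 0.40)
    triplet_input_range: tuple[float, float] = (0.40, 0.60)
    pair_fidelity: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.flip_noise < 0.5):
            raise ValueError("flip_noise must lie in [0, 0.5)")
        for name in ("prevalence_range", "triplet_input_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError(f"{name} must lie within (0, 1)")
        need = 3 * self.n_planted_triplets + 2 * self.n_planted_pairs
        if need > self.n_signs:
            raise ValueError(
                f"{self.n_planted_triplets} triplets and {self.n_planted_pairs} "
                f"pairs need {need} sign columns but only {self.n_signs} exist"
            )


@dataclass(frozen=True)
class GroundTruthManifest:
    """Everything planted into a generated table, for recovery scoring."""

    seed: int
    planted_triplets: tuple[dict, ...] = ()
    planted_pairs: tuple[dict, ...] = ()
    disease_parents: dict[str, tuple[str, ...]] = field(default_factory=dict)
    prevalences: dict[str, float] = field(default_factory=dict)

    def triplet_label_sets(self) -> list[frozenset]:
        return [frozenset(t["labels"]) for t in self.planted_triplets]

    def to_json(self) -> str:
        payload = asdict(self)
        payload["planted_triplets"] = list(payload["planted_triplets"])
        payload["planted_pairs"] = list(payload["planted_pairs"])
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def generate_reference_dataset(net: BayesNet, n: int, seed: int) -> DataMatrix:
    """``n`` ancestral samples from a network as a DataMatrix.

    Columns follow the topological order; deterministic given the seed.
    """
    frame = sample_dataframe(net, n, seed)
    return DataMatrix.from_frame(frame)


def _flip(rng: np.random.Generator, col: np.ndarray, eps: float) -> np.ndarray:
    if eps <= 0:
        return col
    flips = rng.random(col.shape[0]) < eps
    return np.where(flips, 1 - col, col).astype(np.int8)


def _labels(cfg: SurveyGenConfig) -> tuple[list[str], list[str]]:
    signs = [f"sg{i + 1:02d}" for i in range(cfg.n_signs)]
    diseases = [f"dz{i + 1:02d}" for i in range(cfg.n_diseases)]
    return signs, diseases


def generate_survey(cfg: SurveyGenConfig) -> tuple[DataMatrix, GroundTruthManifest]:
    """A survey table with planted pairwise, synergistic and OR-gate structure.

    Mechanisms, in column allocation order over the sign pool:

    - each planted triplet uses three sign columns: two independent
      near-balanced inputs A, B and a target C = XOR(A, B) with independent
      flip probability ``flip_noise``;
    - each planted pair is a noisy copy: the second column equals the first
      with probability ``pair_fidelity``, else its complement;
    - remaining signs are independent with skewed background prevalences;
    - each disease column is the OR of 1-3 randomly chosen non-target signs,
      again flipped with probability ``flip_noise``.
    """
    rng = np.random.default_rng(cfg.seed)
    signs, diseases = _labels(cfg)
    n = cfg.n_subjects
    columns: dict[str, np.ndarray] = {}
    prevalences: dict[str, float] = {}
    pool = list(signs)

    triplets = []
    for _ in range(cfg.n_planted_triplets):
        a, b, c = pool.pop(0), pool.pop(0), pool.pop(0)
        pa, pb = rng.uniform(*cfg.triplet_input_range, size=2)
        col_a = (rng.random(n) < pa).astype(np.int8)
        col_b = (rng.random(n) < pb).astype(np.int8)
        col_c = _flip(rng, (col_a ^ col_b).astype(np.int8), cfg.flip_noise)
        columns[a], columns[b], columns[c] = col_a, col_b, col_c
        prevalences[a], prevalences[b] = float(pa), float(pb)
        triplets.append(
            {
                "labels": (a, b, c),
                "mechanism": "xor",
                "flip_noise": cfg.flip_noise,
                "input_prevalences": (float(pa), float(pb)),
            }
        )

    pairs = []
    for _ in range(cfg.n_planted_pairs):
        src, dst = pool.pop(0), pool.pop(0)
        p = rng.uniform(*cfg.prevalence_range)
        col_src = (rng.random(n) < p).astype(np.int8)
        keep = rng.random(n) < cfg.pair_fidelity
        col_dst = np.where(keep, col_src, 1 - col_src).astype(np.int8)
        columns[src], columns[dst] = col_src, col_dst
        prevalences[src] = float(p)
        pairs.append({"labels": (src, dst), "fidelity": cfg.pair_fidelity})

    for label in pool:
        p = rng.uniform(*cfg.prevalence_range)
        columns[label] = (rng.random(n) < p).astype(np.int8)
        prevalences[label] = float(p)

    # Disease columns: OR gates over signs that are not synergy targets
    # (diseases are downstream inferences from signs, as in the network model).
    target_labels = {t["labels"][2] for t in triplets}
    eligible = [s for s in signs if s not in target_labels]
    disease_parents: dict[str, tuple[str, ...]] = {}
    for label in diseases:
        k = int(rng.integers(1, 4))
        parents = tuple(sorted(rng.choice(eligible, size=k, replace=False)))
        gate = np.zeros(n, dtype=np.int8)
        for parent in parents:
            gate |= columns[parent]
        columns[label] = _flip(rng, gate, cfg.flip_noise)
        disease_parents[label] = parents

    frame = pd.DataFrame({label: columns[label] for label in signs + diseases})
    manifest = GroundTruthManifest(
        seed=cfg.seed,
        planted_triplets=tuple(triplets),
        planted_pairs=tuple(pairs),
        disease_parents=disease_parents,
        prevalences=prevalences,
    )
    return DataMatrix.from_frame(frame), manifest


def generate_null_survey(cfg: SurveyGenConfig) -> tuple[DataMatrix, GroundTruthManifest]:
    """A same-shape table whose columns are all mutually independent.

    Prevalences are drawn from the background range for every column; no
    mechanism of any kind is planted.  Serves as the global-null harness for
    false-positive calibration of the scan.
    """
    rng = np.random.default_rng(cfg.seed)
    signs, diseases = _labels(cfg)
    n = cfg.n_subjects
    columns: dict[str, np.ndarray] = {}
    prevalences: dict[str, float] = {}
    for label in signs + diseases:
        p = rng.uniform(*cfg.prevalence_range)
        columns[label] = (rng.random(n) < p).astype(np.int8)
        prevalences[label] = float(p)
    frame = pd.DataFrame(columns)
    manifest = GroundTruthManifest(seed=cfg.seed, prevalences=prevalences)
    return DataMatrix.from_frame(frame), manifest


def verify_manifest(data: DataMatrix, manifest: GroundTruthManifest) -> None:
    """Assert that every label the manifest mentions exists in the data header."""
    header = set(data.columns)
    mentioned: set[str] = set()
    for t in manifest.planted_triplets:
        mentioned.update(t["labels"])
    for p in manifest.planted_pairs:
        mentioned.update(p["labels"])
    for disease, parents in manifest.disease_parents.items():
        mentioned.add(disease)
        mentioned.update(parents)
    mentioned.update(manifest.prevalences)
    missing = sorted(mentioned - header)
    if missing:
        raise ValueError(f"manifest mentions labels absent from the data: {missing}")
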