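"""Synthetic drug-disease datasets with planted low-rank structure.

The generator emulates the shape of the public drug-repositioning
benchmarks: a sparse binary association matrix whose rows and columns
also come with similarity matrices that are noisy functions of the
same latent factors.  Because the ground-truth association propensity
is returned alongside the sampled labels, every downstream stage
(graph construction, training, cross-validation, cold-start and
ablation protocols) can be tested against a known signal without
downloading any benchmark files.

Construction, for drug factors U (n x r) and disease factors V (m x r)
with i.i.d. standard normal entries:

* true propensity ``s_ij = sigmoid(U_i . V_j - theta)`` with ``theta``
  chosen by bisection so that ``mean(s)`` matches the requested density;
* labels ``Y_ij ~ Bernoulli(s_ij)``;
* drug similarity = ``(1 + cos(U_i, U_j)) / 2`` plus symmetric
  ``N(0, similarity_noise)`` perturbation, clipped to [0, 1], unit
  diagonal; disease similarity analogously from V.

All randomness streams from one seed in a fixed order (U, V, label
uniforms, drug noise, disease noise), so a spec is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import AssociationMatrix, DrugDiseaseDataset, SimilarityMatrix

__all__ = ["SyntheticSpec", "generate_planted_dataset", "planted_dataset",
           "toy_fixture", "toy_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted dataset."""

    n_drugs: int = 100
    n_diseases: int = 80
    latent_rank: int = 4
    density: float = 0.05
    similarity_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank < 1 or self.latent_rank > min(self.n_drugs, self.n_diseases):
            raise ValueError("latent_rank must be in [1, min(n_drugs, n_diseases)]")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie strictly between 0 and 1")
        if self.similarity_noise < 0.0:
            raise ValueError("similarity_noise must be nonnegative")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _solve_threshold(logits: np.ndarray, density: float, tol: float = 1e-3) -> float:
    """Bisection for theta with mean(sigmoid(logits - theta)) ~= density."""
    lo, hi = float(logits.min()) - 50.0, float(logits.max()) + 50.0
    f_lo = _sigmoid(logits - lo).mean() - density   # ~ 1 - density > 0
    f_hi = _sigmoid(logits - hi).mean() - density   # ~ -density < 0
    if f_lo < 0 or f_hi > 0:
        raise ValueError(f"density {density} infeasible for the drawn factors")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        f_mid = _sigmoid(logits - mid).mean() - density
        if abs(f_mid) < tol:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    raise ValueError("threshold search did not converge")


def _cosine_similarity_01(factors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(factors, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = factors / norms
    return (1.0 + unit @ unit.T) / 2.0


def _noisy_similarity(base: np.ndarray, noise_std: float,
                      rng: np.random.Generator) -> np.ndarray:
    n = base.shape[0]
    draw = rng.standard_normal((n, n)) * noise_std
    upper = np.triu(draw, k=1)
    sim = np.clip(base + upper + upper.T, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def generate_planted_dataset(
    spec: SyntheticSpec,
) -> tuple[SimilarityMatrix, SimilarityMatrix, AssociationMatrix, np.ndarray]:
    """Draw one planted dataset; returns the truth propensities as well."""
    rng = np.random.default_rng(spec.seed)
    u = rng.standard_normal((spec.n_drugs, spec.latent_rank))
    v = rng.standard_normal((spec.n_diseases, spec.latent_rank))
    logits = u @ v.T
    theta = _solve_threshold(logits, spec.density)
    truth = _sigmoid(logits - theta)
    labels = (rng.random(truth.shape) < truth).astype(np.int8)
    drug_sim = _noisy_similarity(_cosine_similarity_01(u), spec.similarity_noise, rng)
    disease_sim = _noisy_similarity(_cosine_similarity_01(v), spec.similarity_noise, rng)
    return (
        SimilarityMatrix(drug_sim, entity_kind="drug"),
        SimilarityMatrix(disease_sim, entity_kind="disease"),
        AssociationMatrix(labels),
        truth,
    )


def planted_dataset(spec: SyntheticSpec) -> tuple[DrugDiseaseDataset, np.ndarray]:
    """Convenience: bundle the generated triple into a dataset object."""
    drug_sim, disease_sim, assoc, truth = generate_planted_dataset(spec)
    return DrugDiseaseDataset(drug_sim=drug_sim, disease_sim=disease_sim, assoc=assoc), truth


def toy_fixture() -> tuple[SimilarityMatrix, SimilarityMatrix, AssociationMatrix]:
    """A fixed 3-drug x 2-disease instance used throughout the oracle tests.

    Drug 2 has no associations, which makes it a ready-made cold-start
    case for the new-drug protocol.
    """
    drug_sim = SimilarityMatrix(
        np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]]),
        entity_kind="drug")
    disease_sim = SimilarityMatrix(
        np.array([[1.0, 0.3], [0.3, 1.0]]), entity_kind="disease")
    assoc = AssociationMatrix(np.array([[1, 0], [1, 1], [0, 0]]))
    return drug_sim, disease_sim, assoc


def toy_dataset() -> DrugDiseaseDataset:
    drug_sim, disease_sim, assoc = toy_fixture()
    return DrugDiseaseDataset(drug_sim=drug_sim, disease_sim=disease_sim, assoc=assoc)
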