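"""Synthetic synonymous-codon expression libraries with planted effects.

Emulates the structure of randomized-codon expression libraries: every
variant back-translates the same amino-acid sequence, with codon choices
drawn uniformly over synonyms, weighted by codon speed, or arranged to plant
a bottleneck of a target location and strength.  Simulated measurements then
carry the statistical structure the analysis stage assumes:

* log per-cell abundance responds negatively to the bottleneck's relative
  location and positively to its relative strength when the bottleneck is
  proximal, plus a folding-energy covariate and Gaussian noise;
* OD (the fitness proxy) decreases linearly with the copy numbers of
  designated penalty codons (defaults UCA and CAU) plus Gaussian noise;
* measured protein abundance is per-cell abundance x OD, so dividing by OD
  recovers the per-cell signal exactly in expectation.

Everything is reproducible from the seeds; folding energy is drawn as an
independent covariate (it is an input to the analysis, not computed from
sequence), which also lets tests toggle confounding independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bottleneck import DEFAULT_WINDOW_N, find_bottleneck
from .codon_model import (
    AA_TO_CODONS,
    CodingSequence,
    CodonWeightTable,
)
from .library_stats import LibraryRecord

__all__ = [
    "DEFAULT_AA_SEQUENCE",
    "PlantedBottleneck",
    "LibrarySpec",
    "EffectModel",
    "generate_library",
    "simulate_measurements",
    "default_library",
]

# 239-residue synthetic GFP-like fixture (avGFP-derived, one Gly appended).
DEFAULT_AA_SEQUENCE = (
    "MSKGEELFTGVVPILVELDGDVNGHKFSVSGEGEGDATYGKLTLKFICTTGKLPVPWPTL"
    "VTTFSYGVQCFSRYPDHMKQHDFFKSAMPEGYVQERTIFFKDDGNYKTRAEVKFEGDTLV"
    "NRIELKGIDFKEDGNILGHKLEYNYNSHNVYIMADKQKNGIKVNFKIRHNIEDGSVQLAD"
    "HYQQNTPIGDGPVLLPDNHYLSTQSALSKDPNEKRDHMVLLEFVTAAGITHGMDELYKG"
)

_VALID_POLICIES = ("uniform_synonymous", "frequency_weighted", "planted_bottleneck")


@dataclass(frozen=True)
class PlantedBottleneck:
    """Target bottleneck geometry for the planted_bottleneck policy."""

    relative_location: float
    relative_strength: float
    window_n: int = DEFAULT_WINDOW_N

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_location <= 1.0:
            raise ValueError("planted relative_location must be in (0, 1]")
        if self.relative_strength < 1.0:
            raise ValueError("planted relative_strength must be >= 1")
        if self.window_n < 1:
            raise ValueError("planted window_n must be >= 1")


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for a synonymous-variant library."""

    aa_sequence: str = DEFAULT_AA_SEQUENCE
    n_variants: int = 150
    seed: int = 0
    codon_policy: str = "uniform_synonymous"
    planted: PlantedBottleneck | None = None

    def __post_init__(self) -> None:
        if self.n_variants < 3:
            raise ValueError("a library needs at least 3 variants")
        bad = sorted(set(self.aa_sequence) - set(AA_TO_CODONS))
        if bad:
            raise ValueError(f"non-standard amino acid letters {bad}")
        if self.codon_policy not in _VALID_POLICIES:
            raise ValueError(
                f"unknown codon policy {self.codon_policy!r}; expected one of {_VALID_POLICIES}"
            )
        if self.codon_policy == "planted_bottleneck" and self.planted is None:
            raise ValueError("planted_bottleneck policy requires planted targets")


@dataclass(frozen=True)
class EffectModel:
    """Generative truth for the simulated measurements.

    Log per-cell abundance:
        b0 + beta_location * rel_loc
           + beta_strength_proximal * (rel_str - strength_reference)
                                    * 1[rel_loc <= proximal_cutoff]
           + beta_folding * folding_energy + N(0, noise_sd_abundance)
    OD:
        od_baseline - sum_c gamma[c] * count_c + N(0, noise_sd_od), floored.

    The strength term is referenced to a typical relative strength
    (``strength_reference``) so crossing the proximal cutoff does not create
    a spurious step in abundance; within the proximal region the slope in
    relative strength is ``beta_strength_proximal``.  Defaults are sized so
    that at 150 variants the planted bottleneck and penalty-codon
    correlations land at moderate, realistic magnitudes (|r| roughly
    0.3-0.5).
    """

    beta_location: float = -0.7
    beta_strength_proximal: float = 2.4
    strength_reference: float = 1.3
    proximal_cutoff: float = 0.28
    beta_folding: float = 0.08  # per kcal/mol; stable (more negative) folds lower abundance
    gamma: Mapping[str, float] = field(
        default_factory=lambda: {"UCA": 0.05, "CAU": 0.04}
    )
    noise_sd_abundance: float = 0.35
    noise_sd_od: float = 0.08
    od_baseline: float = 1.5
    od_floor: float = 0.05
    log_abundance_baseline: float = 3.0
    folding_mean: float = -8.0
    folding_sd: float = 2.0
    window_n: int = DEFAULT_WINDOW_N

    def __post_init__(self) -> None:
        if self.beta_location > 0:
            raise ValueError("beta_location must be <= 0 (proximal helps)")
        if self.beta_strength_proximal < 0:
            raise ValueError("beta_strength_proximal must be >= 0")
        if any(g < 0 for g in self.gamma.values()):
            raise ValueError("per-codon OD penalties must be >= 0")
        if self.noise_sd_abundance <= 0 or self.noise_sd_od <= 0:
            raise ValueError("noise standard deviations must be > 0")
        if self.od_baseline <= 0 or self.od_floor <= 0:
            raise ValueError("od_baseline and od_floor must be > 0")

    def null(self) -> "EffectModel":
        """Copy with all planted effects zeroed (noise retained)."""
        return EffectModel(
            beta_location=0.0,
            beta_strength_proximal=0.0,
            strength_reference=self.strength_reference,
            proximal_cutoff=self.proximal_cutoff,
            beta_folding=0.0,
            gamma={},
            noise_sd_abundance=self.noise_sd_abundance,
            noise_sd_od=self.noise_sd_od,
            od_baseline=self.od_baseline,
            od_floor=self.od_floor,
            log_abundance_baseline=self.log_abundance_baseline,
            folding_mean=self.folding_mean,
            folding_sd=self.folding_sd,
            window_n=self.window_n,
        )


def _position_time_stats(codons: Sequence[str], weights: CodonWeightTable):
    times = np.array([1.0 / weights[c] for c in codons])
    return times, float(times.mean()), float(times.max()), float(times.min())


def _solve_inside_mix(
    per_pos: list[tuple[np.ndarray, float, float, float]],
    inside: np.ndarray,
    target_rel_strength: float,
    n: int,
    l: int,
    q_out: float = 0.8,
) -> float:
    """Mixing weight q for slow-codon choice inside the planted window.

    Inside the window each position picks its slowest synonym with
    probability q, otherwise uniformly; outside, the fastest synonym with
    probability ``q_out``.  q is solved by bisection so the expected relative
    strength matches the target; if the target is unreachable even at q = 1 a
    warning is issued and q = 1 is used (best effort).
    """
    e_in_uniform = np.array([m for _, m, _, _ in per_pos])
    e_slowest = np.array([mx for _, _, mx, _ in per_pos])
    e_fastest = np.array([mn for _, _, _, mn in per_pos])
    out_expected = q_out * e_fastest + (1 - q_out) * e_in_uniform

    def rel_strength(q: float) -> float:
        exp_time = np.where(inside, q * e_slowest + (1 - q) * e_in_uniform, out_expected)
        window_mean = exp_time[inside].mean()
        return float(window_mean / exp_time.mean())

    lo_val, hi_val = rel_strength(0.0), rel_strength(1.0)
    if target_rel_strength >= hi_val:
        if target_rel_strength > hi_val + 1e-9:
            warnings.warn(
                f"planted relative strength {target_rel_strength:.3g} unreachable "
                f"(max {hi_val:.3g}); using the strongest attainable window",
                stacklevel=2,
            )
        return 1.0
    if target_rel_strength <= lo_val:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if rel_strength(mid) < target_rel_strength:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_library(
    spec: LibrarySpec, weights: CodonWeightTable
) -> list[CodingSequence]:
    """Draw ``spec.n_variants`` synonymous codon sequences for the protein.

    Every variant translates back to ``spec.aa_sequence`` (checked).  Under
    ``planted_bottleneck`` the synonym choices inside the target window favor
    the slowest codons and elsewhere the fastest, with the inside mixing
    weight solved so the expected relative strength matches the target.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    aas = list(spec.aa_sequence)
    l = len(aas)
    syn = [AA_TO_CODONS[aa] for aa in aas]
    per_pos = [_position_time_stats(codons, weights) for codons in syn]

    inside = np.zeros(l, dtype=bool)
    q_in = 0.0
    q_out = 0.8
    if spec.codon_policy == "planted_bottleneck":
        planted = spec.planted
        n = planted.window_n
        if l < n:
            raise ValueError(f"protein of {l} codons shorter than planted window {n}")
        n_windows = l - n + 1
        k0 = min(max(1, round(planted.relative_location * n_windows)), n_windows)
        inside[k0 - 1 : k0 - 1 + n] = True
        q_in = _solve_inside_mix(per_pos, inside, planted.relative_strength, n, l, q_out)

    choice_matrix = np.empty((spec.n_variants, l), dtype=np.int16)
    for j, codons in enumerate(syn):
        k = len(codons)
        times = per_pos[j][0]
        if spec.codon_policy == "uniform_synonymous":
            p = np.full(k, 1.0 / k)
        elif spec.codon_policy == "frequency_weighted":
            w = 1.0 / times
            p = w / w.sum()
        else:  # planted_bottleneck
            p = np.full(k, 1.0 / k)
            if inside[j]:
                if k > 1:
                    p = p * (1 - q_in)
                    p[int(np.argmax(times))] += q_in
            else:
                if k > 1:
                    p = p * (1 - q_out)
                    p[int(np.argmin(times))] += q_out
        choice_matrix[:, j] = rng.choice(k, size=spec.n_variants, p=p)

    variants = []
    for i in range(spec.n_variants):
        codons = tuple(syn[j][choice_matrix[i, j]] for j in range(l))
        seq = CodingSequence(id=f"var{i:04d}", codons=codons)
        if seq.translate() != spec.aa_sequence:  # translation fidelity enforced
            raise AssertionError("back-translation failed to preserve the protein")
        variants.append(seq)
    return variants


def simulate_measurements(
    variants: Sequence[CodingSequence],
    weights: CodonWeightTable,
    model: EffectModel | None = None,
    seed: int = 0,
) -> list[LibraryRecord]:
    """Simulate abundance/OD/folding measurements for a variant set."""
    if len(variants) < 3:
        raise ValueError("measurement simulation requires >= 3 variants")
    model = model if model is not None else EffectModel()
    rng = np.random.default_rng(seed)
    n_var = len(variants)

    rel_loc = np.empty(n_var)
    rel_str = np.empty(n_var)
    for i, seq in enumerate(variants):
        bn = find_bottleneck(seq, weights, n=model.window_n)
        rel_loc[i] = bn.relative_location
        rel_str[i] = bn.relative_strength

    folding = rng.normal(model.folding_mean, model.folding_sd, n_var)
    abundance_noise = rng.normal(0.0, model.noise_sd_abundance, n_var)
    od_noise = rng.normal(0.0, model.noise_sd_od, n_var)

    proximal = rel_loc <= model.proximal_cutoff
    log_per_cell = (
        model.log_abundance_baseline
        + model.beta_location * rel_loc
        + model.beta_strength_proximal * (rel_str - model.strength_reference) * proximal
        + model.beta_folding * folding
        + abundance_noise
    )
    per_cell = np.exp(log_per_cell)

    penalty = np.zeros(n_var)
    for codon, gamma in model.gamma.items():
        counts = np.array([seq.codons.count(codon) for seq in variants], dtype=float)
        penalty += gamma * counts
    od_raw = model.od_baseline - penalty + od_noise
    floored = od_raw < model.od_floor
    if floored.mean() > 0.10:
        raise ValueError(
            f"OD floor hit for {floored.mean():.0%} of variants; "
            "reduce penalties or raise od_baseline"
        )
    od = np.maximum(od_raw, model.od_floor)

    return [
        LibraryRecord(
            variant_id=seq.id,
            seq=seq,
            protein_abundance=float(per_cell[i] * od[i]),
            od=float(od[i]),
            folding_energy=float(folding[i]),
        )
        for i, seq in enumerate(variants)
    ]


def default_library(
    weights: CodonWeightTable,
    seed: int = 0,
    n_variants: int = 150,
    model: EffectModel | None = None,
) -> list[LibraryRecord]:
    """The default study library: uniform synonymous variants of the GFP-like
    protein with measurements from the default effect model.  Sequence and
    measurement seeds are derived from ``seed`` so one integer reproduces
    everything."""
    spec = LibrarySpec(n_variants=n_variants, seed=seed, codon_policy="uniform_synonymous")
    variants = generate_library(spec, weights)
    return simulate_measurements(variants, weights, model=model, seed=seed + 1_000_003)
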