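"""Synthetic genotype-phenotype study generator.

Generates studies with the structure the analysis assumes: breeds of fixed
size, biallelic loci with per-breed genotype distributions, and traits built
as breed baseline + per-locus genotype value + Gaussian noise, truncated at
zero. The default configuration reproduces the reference study design
(117 hens in breeds PH=59, C=20, BB=20, LC=18; seven NPY coding-region SNPs
with the published per-breed genotype frequencies, which carry their
Hardy-Weinberg deviations; eight egg-production traits with the published
per-breed means and SDs; no genotype effects).

Genotype distributions are specified either directly as genotype-class
frequencies (frequency-table mode) or through an allele frequency p plus an
inbreeding-style deviation parameter F, giving class probabilities
(p^2 + Fpq, 2pq(1-F), q^2 + Fpq); F = 0 is Hardy-Weinberg, F = 1 removes
heterozygotes.

Randomness is fully reproducible: every (stage, locus, breed) or
(stage, trait, breed) cell draws from its own substream derived from the
single study seed, so adding loci or traits never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .core_data import (
    GenotypeCall,
    GenotypeTable,
    LocusDef,
    SampleRecord,
    STUDY_TRAITS,
    TraitDef,
    TraitTable,
    write_genotype_table,
    write_trait_table,
)

__all__ = [
    "ConfigError",
    "GenotypeModel",
    "LocusSim",
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "generate_study",
    "default_config",
    "null_calibration_config",
    "power_config",
]


class ConfigError(ValueError):
    """A simulation configuration is inconsistent."""


@dataclass(frozen=True)
class GenotypeModel:
    """Genotype-class distribution for one locus in one breed.

    Either ``freqs`` gives the three class probabilities directly, or ``p``
    (ref-allele frequency) with deviation ``f`` gives
    (p^2 + Fpq, 2pq(1-F), q^2 + Fpq).
    """

    p: float | None = None
    f: float = 0.0
    freqs: tuple | None = None

    def probabilities(self) -> tuple:
        if self.freqs is not None:
            probs = tuple(float(x) for x in self.freqs)
        else:
            if self.p is None:
                raise ConfigError("GenotypeModel needs either p or freqs")
            p, q = float(self.p), 1.0 - float(self.p)
            probs = (
                p * p + self.f * p * q,
                2 * p * q * (1 - self.f),
                q * q + self.f * p * q,
            )
        if min(probs) < -1e-12 or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"genotype probabilities invalid (p={self.p}, F={self.f}, freqs={self.freqs}): {probs}"
            )
        return tuple(max(x, 0.0) for x in probs)


@dataclass(frozen=True)
class LocusSim:
    """One simulated locus: definition plus per-breed genotype model."""

    locus: LocusDef
    models: dict  # breed -> GenotypeModel


@dataclass
class SimConfig:
    """Full study recipe: breeds, loci, trait model, effects, seed.

    ``trait_baselines[trait][breed] = (mean, sd)``;
    ``effects[(locus_id, trait)] = (a, d)`` adds genotype values
    (-a, d, +a) for ref-hom / het / alt-hom to the trait.
    """

    breeds: tuple
    loci: list
    trait_baselines: dict
    effects: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.breeds or any(n < 1 for _, n in self.breeds):
            raise ConfigError("every breed needs n >= 1")
        breed_labels = [b for b, _ in self.breeds]
        for ls in self.loci:
            for breed in breed_labels:
                if breed not in ls.models:
                    raise ConfigError(f"locus {ls.locus.locus_id}: no model for breed {breed!r}")
                ls.models[breed].probabilities()
        for trait, per_breed in self.trait_baselines.items():
            for breed in breed_labels:
                if breed not in per_breed:
                    raise ConfigError(f"trait {trait}: no baseline for breed {breed!r}")

    @property
    def trait_names(self) -> list:
        return list(self.trait_baselines)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "breeds": [[b, int(n)] for b, n in self.breeds],
            "loci": [
                {
                    "locus_id": ls.locus.locus_id,
                    "position": ls.locus.position,
                    "ref": ls.locus.ref_allele,
                    "alt": ls.locus.alt_allele,
                    "models": {
                        breed: (
                            {"freqs": list(m.freqs)}
                            if m.freqs is not None
                            else {"p": m.p, "f": m.f}
                        )
                        for breed, m in ls.models.items()
                    },
                }
                for ls in self.loci
            ],
            "trait_baselines": {
                t: {b: list(ms) for b, ms in per.items()}
                for t, per in self.trait_baselines.items()
            },
            "effects": [
                {"locus": lid, "trait": t, "a": a, "d": d}
                for (lid, t), (a, d) in self.effects.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        loci = [
            LocusSim(
                LocusDef(e["locus_id"], int(e["position"]), e["ref"], e["alt"]),
                {
                    breed: (
                        GenotypeModel(freqs=tuple(m["freqs"]))
                        if "freqs" in m
                        else GenotypeModel(p=float(m["p"]), f=float(m.get("f", 0.0)))
                    )
                    for breed, m in e["models"].items()
                },
            )
            for e in d["loci"]
        ]
        effects = {
            (e["locus"], e["trait"]): (float(e["a"]), float(e["d"]))
            for e in d.get("effects", [])
        }
        return cls(
            breeds=tuple((b, int(n)) for b, n in d["breeds"]),
            loci=loci,
            trait_baselines={
                t: {b: tuple(ms) for b, ms in per.items()}
                for t, per in d["trait_baselines"].items()
            },
            effects=effects,
            seed=int(d.get("seed", 0)),
        )


@dataclass
class SimTruth:
    """Generating parameters and per-sample latent genetic values."""

    config: dict
    genetic_values: pd.DataFrame  # index sample_id, columns traits


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


_STAGE_GENOTYPE = 1
_STAGE_NOISE = 2


def simulate_genotypes(cfg: SimConfig) -> GenotypeTable:
    """Draw a genotype table; independent samples per breed x locus cell.

    Each cell uses substream (seed, 1, locus_index, breed_index); draws are
    inverse-CDF on a uniform stream, so a brute-force sampler reading the
    same stream reproduces the calls exactly.
    """
    cfg.validate()
    samples = []
    for breed, n in cfg.breeds:
        for i in range(n):
            samples.append(SampleRecord(f"{breed}{i + 1:03d}", breed, {}))
    offsets = {}
    off = 0
    for breed, n in cfg.breeds:
        offsets[breed] = off
        off += n
    for li, ls in enumerate(cfg.loci):
        locus = ls.locus
        geno_strings = (
            locus.ref_allele * 2,
            "".join(sorted(locus.ref_allele + locus.alt_allele)),
            locus.alt_allele * 2,
        )
        for bi, (breed, n) in enumerate(cfg.breeds):
            probs = ls.models[breed].probabilities()
            c0, c1 = probs[0], probs[0] + probs[1]
            u = _rng(cfg.seed, _STAGE_GENOTYPE, li, bi).random(n)
            codes = (u >= c0).astype(int) + (u >= c1).astype(int)
            for i, code in enumerate(codes):
                samples[offsets[breed] + i].calls[locus.locus_id] = GenotypeCall.from_string(
                    geno_strings[code]
                )
    return GenotypeTable([ls.locus for ls in cfg.loci], samples)


def _genotype_value(call: GenotypeCall, locus: LocusDef, a: float, d: float) -> float:
    if call is None or call.is_missing:
        return 0.0
    if call.is_het:
        return d
    return -a if call.alleles[0] == locus.ref_allele else a


def simulate_phenotypes(genotypes: GenotypeTable, cfg: SimConfig) -> tuple:
    """Trait values = breed baseline + genotype values + noise, clipped at 0.

    Noise for trait t in breed b uses substream (seed, 2, t_index, b_index).
    Returns ``(TraitTable, SimTruth)``.
    """
    cfg.validate()
    breed_labels = [b for b, _ in cfg.breeds]
    for s in genotypes.samples:
        if s.breed not in breed_labels:
            raise ConfigError(f"genotype table contains unknown breed {s.breed!r}")
    loci_by_id = {ls.locus.locus_id: ls.locus for ls in cfg.loci}
    traits = cfg.trait_names
    genetic = {s.sample_id: {t: 0.0 for t in traits} for s in genotypes.samples}
    for (locus_id, trait), (a, d) in cfg.effects.items():
        if locus_id not in loci_by_id:
            raise ConfigError(f"effect references unknown locus {locus_id!r}")
        if trait not in traits:
            raise ConfigError(f"effect references unknown trait {trait!r}")
        locus = loci_by_id[locus_id]
        for s in genotypes.samples:
            genetic[s.sample_id][trait] += _genotype_value(
                s.calls.get(locus_id), locus, a, d
            )
    values: dict = {}
    for ti, trait in enumerate(traits):
        for bi, (breed, _) in enumerate(cfg.breeds):
            members = [s for s in genotypes.samples if s.breed == breed]
            mean, sd = cfg.trait_baselines[trait][breed]
            noise = _rng(cfg.seed, _STAGE_NOISE, ti, bi).normal(0.0, sd, size=len(members))
            for s, e in zip(members, noise):
                v = mean + genetic[s.sample_id][trait] + float(e)
                values.setdefault(s.sample_id, {})[trait] = max(v, 0.0)
    by_name = {t.name: t for t in STUDY_TRAITS}
    trait_defs = tuple(by_name.get(name, TraitDef(name)) for name in traits)
    table = TraitTable(trait_defs, {s.sample_id: values[s.sample_id] for s in genotypes.samples})
    truth = SimTruth(
        cfg.to_dict(),
        pd.DataFrame.from_dict(genetic, orient="index")[traits],
    )
    return table, truth


def generate_study(cfg: SimConfig, outdir) -> dict:
    """Simulate and write a full study to ``outdir``.

    Writes ``genotypes.tsv``, ``traits.tsv``, ``truth.tsv`` (per-sample
    latent genetic values) and ``config.yaml`` (the effective config echo).
    Byte-identical for identical configs. Returns the file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(cfg)
    traits, truth = simulate_phenotypes(genotypes, cfg)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "traits": outdir / "traits.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_genotype_table(genotypes, paths["genotypes"])
    write_trait_table(traits, paths["traits"])
    truth.genetic_values.rename_axis("sample_id").to_csv(paths["truth"], sep="\t")
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Stock configurations


def _study_breeds() -> tuple:
    return tuple((b, datasets.BREED_SIZES[b]) for b in datasets.BREEDS)


def default_config(seed: int = 0) -> SimConfig:
    """The reference study design: per-breed published genotype frequencies
    (frequency-table mode, carrying their HWE deviations), per-breed
    published trait baselines, no genotype effects."""
    loci = []
    for locus in datasets.STUDY_LOCI:
        models = {}
        for breed in datasets.BREEDS:
            counts = datasets.GENOTYPE_COUNTS[(locus.locus_id, breed)]
            n = sum(counts)
            models[breed] = GenotypeModel(freqs=tuple(c / n for c in counts))
        loci.append(LocusSim(locus, models))
    return SimConfig(
        breeds=_study_breeds(),
        loci=loci,
        trait_baselines={t: dict(per) for t, per in datasets.TRAIT_BASELINES.items()},
        seed=seed,
    )


def _pooled_freq_models() -> list:
    """Per-locus genotype models shared across breeds (pooled study counts),
    making genotype independent of breed."""
    loci = []
    for locus in datasets.STUDY_LOCI:
        totals = [0, 0, 0]
        for breed in datasets.BREEDS:
            for i, c in enumerate(datasets.GENOTYPE_COUNTS[(locus.locus_id, breed)]):
                totals[i] += c
        n = sum(totals)
        model = GenotypeModel(freqs=tuple(c / n for c in totals))
        loci.append(LocusSim(locus, {b: model for b in datasets.BREEDS}))
    return loci


def null_calibration_config(seed: int = 0) -> SimConfig:
    """Null study for type-I calibration of the pooled genotype scan.

    Keeps the study's breed sizes and per-breed trait baselines but shares
    each locus's pooled genotype frequencies across breeds, so genotype is
    independent of trait under the null. (With breed-specific genotype
    frequencies the pooled one-way model is confounded by breed
    stratification, which is a property of that design, not of the test.)
    """
    return SimConfig(
        breeds=_study_breeds(),
        loci=_pooled_freq_models(),
        trait_baselines={t: dict(per) for t, per in datasets.TRAIT_BASELINES.items()},
        seed=seed,
    )


def pooled_within_sd(trait: str) -> float:
    """Pooled within-breed SD of a trait under the published baselines."""
    num = den = 0.0
    for breed in datasets.BREEDS:
        n = datasets.BREED_SIZES[breed]
        _, sd = datasets.TRAIT_BASELINES[trait][breed]
        num += (n - 1) * sd * sd
        den += n - 1
    return math.sqrt(num / den)


def grand_mean(trait: str) -> float:
    """Sample-size-weighted grand mean of a trait's published baselines."""
    num = den = 0.0
    for breed in datasets.BREEDS:
        n = datasets.BREED_SIZES[breed]
        mean, _ = datasets.TRAIT_BASELINES[trait][breed]
        num += n * mean
        den += n
    return num / den


def power_config(
    seed: int = 0,
    locus_id: str = "SNP3",
    trait: str = "AFEP",
    effect_residual_sds: float = 1.0,
) -> SimConfig:
    """Study with one additive genotype effect, in residual-SD units.

    Baselines are homogenized (grand mean, pooled within-breed SD for every
    breed) so the generator's noise SD *is* the fitted model's residual SD,
    and the injected additive allele effect a equals
    ``effect_residual_sds`` x that SD (hom-hom LS-mean gap 2a). Genotype
    frequencies are the pooled study frequencies, shared across breeds.
    """
    baselines = {
        t: {b: (grand_mean(t), pooled_within_sd(t)) for b in datasets.BREEDS}
        for t in datasets.TRAIT_BASELINES
    }
    sd = pooled_within_sd(trait)
    return SimConfig(
        breeds=_study_breeds(),
        loci=_pooled_freq_models(),
        trait_baselines=baselines,
        effects={(locus_id, trait): (effect_residual_sds * sd, 0.0)},
        seed=seed,
    )
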