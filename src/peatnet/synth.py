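"""Synthetic compositional communities with planted statistical structure.

The generator makes every downstream stage testable without the deposited
sequencing data. It emulates, at the count-table level, the features the
analysis depends on:

* a logistic-normal-multinomial community: per-taxon latent log-abundances
  drawn from a multivariate normal whose correlation matrix has block
  structure (planted co-occurrence modules), pushed through a softmax and
  sampled as multinomial counts at a fixed sequencing depth — the same
  log-ratio generative family that compositionally robust correlation
  estimation assumes;
* soil traits built as the standardized mean latent signal of a target
  module plus Gaussian noise, with the noise variance solved in closed form
  (``var_noise = var_signal * (1/r^2 - 1)``) so the population correlation
  between trait and module signal equals the requested value exactly;
* a taxonomy table in which a configurable fraction of non-module taxa are
  labelled Archaea, to exercise the domain filter.

Everything is driven by one integer seed; identical configuration yields
bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .design import DesignSpec, generate_design
from .otu import OtuTable

__all__ = [
    "SynthConfig",
    "Scenario",
    "SyntheticDataset",
    "generate_counts",
    "generate_traits",
    "planted_partition",
    "load_scenario",
    "list_scenarios",
    "simulate_scenario",
]

#: Traits emitted by default, in output order. Unlinked traits are
#: independent noise on their documented scale.
DEFAULT_TRAITS = (
    "CMR",
    "phenolics",
    "carbohydrates",
    "DOC",
    "FTIR_1630_1030",
    "SOC",
    "TN",
    "TP",
    "AN",
    "AP",
    "pH",
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic community.

    ``module_spec`` lists planted blocks as (size, within_correlation)
    pairs; taxa not in any block are independent. ``trait_links`` lists
    (trait_name, module_index, target_pearson_r) associations between a
    trait and the standardized mean latent signal of a module; traits not
    listed are independent noise with standard deviation ``noise_sd``.
    """

    n_taxa: int = 100
    sequencing_depth: int = 2000
    module_spec: tuple[tuple[int, float], ...] = ()
    trait_links: tuple[tuple[str, int, float], ...] = ()
    noise_sd: float = 1.0
    seed: int = 0
    archaea_fraction: float = 0.0
    traits: tuple[str, ...] = DEFAULT_TRAITS
    trait_scales: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.sequencing_depth < 1:
            raise ValueError("n_taxa and sequencing_depth must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.archaea_fraction < 1.0:
            raise ValueError("archaea_fraction must be in [0, 1)")
        sizes = [size for size, _ in self.module_spec]
        if any(size < 2 for size in sizes):
            raise ValueError("module sizes must be >= 2")
        if sum(sizes) > self.n_taxa:
            raise ValueError(
                f"module sizes sum to {sum(sizes)} but n_taxa = {self.n_taxa}"
            )
        for _, corr in self.module_spec:
            # c = 1 makes the implied block correlation matrix singular
            # (non-positive-definite); c < 0 is outside the planted-block
            # family supported here.
            if not 0.0 <= corr < 1.0:
                raise ValueError(
                    "within_correlation must be in [0, 1): the implied "
                    f"correlation matrix is not positive definite for {corr}"
                )
        for name, module, r in self.trait_links:
            if not (0 <= module < len(self.module_spec)):
                raise ValueError(f"trait {name!r} links to unknown module {module}")
            if abs(r) >= 1.0:
                raise ValueError(f"|target_pearson_r| must be < 1, got {r} for {name!r}")

    @property
    def taxon_ids(self) -> list[str]:
        width = max(4, len(str(self.n_taxa)))
        return [f"OTU{i + 1:0{width}d}" for i in range(self.n_taxa)]


def planted_partition(config: SynthConfig) -> pd.Series:
    """Planted module label per block-member taxon (ground truth for ARI)."""
    ids = config.taxon_ids
    labels, start = {}, 0
    for m, (size, _) in enumerate(config.module_spec):
        for i in range(start, start + size):
            labels[ids[i]] = m
        start += size
    return pd.Series(labels, name="planted_module", dtype="int64")


def _rng_streams(config: SynthConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def _latent_abundances(n_samples: int, config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-taxon baselines and latent deviations (taxa x samples).

    Baseline means are Normal(0, 1) once per taxon, so taxa differ in
    average abundance. Block members share a common factor: for a block
    with within-correlation c, ``z = sqrt(c) * f_block + sqrt(1 - c) * e``,
    which realises the exchangeable block correlation matrix exactly.
    """
    rng = _rng_streams(config)[0]
    p = config.n_taxa
    mu = rng.normal(0.0, 1.0, size=p)
    shared = [rng.normal(size=n_samples) for _ in config.module_spec]
    z = rng.normal(size=(p, n_samples))
    start = 0
    for (size, corr), f in zip(config.module_spec, shared):
        block = slice(start, start + size)
        z[block] = math.sqrt(corr) * f[None, :] + math.sqrt(1.0 - corr) * z[block]
        start += size
    return mu, z


_ARCHAEAL_LINEAGE = (
    "d__Archaea;p__Crenarchaeota;c__Nitrososphaeria;o__Nitrososphaerales;"
    "f__Nitrososphaeraceae;g__Synthetic_archaeon;s__synthetic"
)
_BACTERIAL_PHYLA = (
    "Proteobacteria",
    "Acidobacteriota",
    "Chloroflexi",
    "Actinobacteriota",
    "Bacteroidota",
    "Verrucomicrobiota",
)


def _taxonomy(config: SynthConfig) -> pd.Series:
    """Synthetic 7-rank lineages; archaea drawn from taxa outside planted blocks.

    Keeping planted-module members bacterial means the archaea filter never
    disturbs the planted correlation structure (the filter runs before
    network inference in the pipeline).
    """
    ids = config.taxon_ids
    n_archaea = int(round(config.archaea_fraction * config.n_taxa))
    first_free = sum(size for size, _ in config.module_spec)
    free = list(range(first_free, config.n_taxa))
    if n_archaea > len(free):
        raise ValueError(
            f"archaea_fraction requests {n_archaea} archaea but only "
            f"{len(free)} taxa are outside planted modules"
        )
    archaea = set(free[-n_archaea:]) if n_archaea else set()
    lineages = []
    for i, taxon in enumerate(ids):
        if i in archaea:
            lineages.append(_ARCHAEAL_LINEAGE)
        else:
            phylum = _BACTERIAL_PHYLA[i % len(_BACTERIAL_PHYLA)]
            lineages.append(
                f"d__Bacteria;p__{phylum};c__Synthetic_class;o__Synthetic_order;"
                f"f__Synthetic_family;g__Synthetic_genus;s__{taxon}"
            )
    return pd.Series(lineages, index=ids, name="taxonomy")


def generate_counts(metadata: pd.DataFrame, config: SynthConfig) -> OtuTable:
    """Compositional counts for every sample in ``metadata``.

    Latent log-abundances are softmax-transformed per sample and counts
    drawn by multinomial sampling at ``sequencing_depth``, so every sample
    sums exactly to the depth. Bit-identical under a fixed seed.
    """
    n = len(metadata)
    mu, z = _latent_abundances(n, config)
    logits = mu[:, None] + z
    logits -= logits.max(axis=0, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=0, keepdims=True)
    rng = _rng_streams(config)[1]
    counts = np.column_stack(
        [rng.multinomial(config.sequencing_depth, probs[:, j]) for j in range(n)]
    )
    frame = pd.DataFrame(counts, index=config.taxon_ids, columns=metadata.index)
    table = OtuTable(frame, _taxonomy(config))
    table.log(
        f"synthesised {config.n_taxa} taxa x {n} samples at depth "
        f"{config.sequencing_depth} (seed {config.seed})"
    )
    return table


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    return (x - mean) / sd


def generate_traits(
    metadata: pd.DataFrame, counts: OtuTable, config: SynthConfig
) -> pd.DataFrame:
    """Soil trait table with planted trait-module correlations.

    Each linked trait is the standardized mean latent signal of its target
    module plus Gaussian noise with ``sd = sqrt(1/r^2 - 1)`` (unit signal
    variance), which makes the population correlation with the module
    signal exactly ``target_pearson_r``; a negative target flips the sign
    of the signal term. Unlinked traits are independent
    Normal(0, noise_sd). Each trait is finally mapped onto its documented
    location/scale, which leaves every correlation untouched.

    ``counts`` is accepted for interface symmetry (traits belong to the
    same community draw); the trait signal comes from the latent layer,
    which is re-derived deterministically from the same seed.
    """
    n = len(metadata)
    if counts is not None and list(counts.samples) != list(metadata.index):
        raise ValueError("counts and metadata sample IDs disagree")
    _, z = _latent_abundances(n, config)
    z_std = _standardize(z, axis=1)
    signals = []
    start = 0
    for size, _ in config.module_spec:
        signals.append(_standardize(z_std[start : start + size].mean(axis=0)))
        start += size
    links = {name: (module, r) for name, module, r in config.trait_links}
    rng = _rng_streams(config)[2]
    data = {}
    for trait in config.traits:
        module_r = links.get(trait)
        if module_r is not None and module_r[1] != 0.0:
            module, r = module_r
            noise_sd = math.sqrt(1.0 / (r * r) - 1.0)
            raw = math.copysign(1.0, r) * signals[module] + rng.normal(0.0, noise_sd, n)
            raw = raw * abs(r)  # back to unit variance; correlations unchanged
        else:
            raw = rng.normal(0.0, config.noise_sd, n) / config.noise_sd
        loc, scale = config.trait_scales.get(trait, (0.0, 1.0))
        data[trait] = loc + scale * raw
    traits = pd.DataFrame(data, index=metadata.index)
    traits.index.name = "sample_id"
    return traits


# -- scenarios -----------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A named study condition: one land-use group plus its generator config.

    Scenario files record the planted trait-CMR correlations directly; the
    loader converts them to trait-module links by anchoring CMR to its
    module at ``cmr_module_r`` and giving each trait
    ``r_trait_module = r_trait_cmr / cmr_module_r`` (independent trait
    noises make the trait-trait correlation the product of the two
    trait-module correlations).
    """

    name: str
    land_use: str
    design: DesignSpec
    config: SynthConfig


@dataclass(frozen=True)
class SyntheticDataset:
    metadata: pd.DataFrame
    table: OtuTable
    traits: pd.DataFrame
    config: SynthConfig


def list_scenarios() -> list[str]:
    root = resources.files("peatnet.scenarios")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name: str, seed: int = 0) -> Scenario:
    """Load a packaged scenario (``natural`` or ``cultivated``) or a path."""
    if name.endswith((".yaml", ".yml")):
        text = open(name).read()
    else:
        text = resources.files("peatnet.scenarios").joinpath(f"{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    design = DesignSpec(**raw.get("design", {}))
    anchor_module = int(raw["cmr_module"])
    anchor_r = float(raw["cmr_module_r"])
    links = [("CMR", anchor_module, anchor_r)]
    for trait, r_with_cmr in (raw.get("trait_cmr_r") or {}).items():
        r_module = float(r_with_cmr) / anchor_r
        if abs(r_module) >= 1.0:
            raise ValueError(
                f"planted trait-CMR correlation {r_with_cmr} for {trait!r} is not "
                f"attainable with cmr_module_r = {anchor_r}"
            )
        links.append((trait, anchor_module, r_module))
    config = SynthConfig(
        n_taxa=int(raw["n_taxa"]),
        sequencing_depth=int(raw["sequencing_depth"]),
        module_spec=tuple((int(s["size"]), float(s["within_correlation"])) for s in raw["modules"]),
        trait_links=tuple(links),
        noise_sd=float(raw.get("noise_sd", 1.0)),
        seed=seed,
        archaea_fraction=float(raw.get("archaea_fraction", 0.0)),
        trait_scales={k: tuple(v) for k, v in (raw.get("trait_scales") or {}).items()},
    )
    return Scenario(name=raw["name"], land_use=raw["land_use"], design=design, config=config)


def trait_correlation_replicates(
    scenario_name: str,
    trait_a: str,
    trait_b: str,
    n_replicates: int = 200,
    base_seed: int = 0,
) -> np.ndarray:
    """Empirical Pearson r between two traits over seeded scenario replicates.

    Each replicate regenerates the scenario's land-use group (n = 24 samples
    by default) with an independent child seed and computes the sample
    correlation; the mean over replicates estimates the planted
    association. Only the trait layer is generated (counts are not needed
    for a trait-trait correlation).
    """
    from .stats import pearson_with_p

    scenario = load_scenario(scenario_name, seed=base_seed)
    full = generate_design(scenario.design)
    metadata = full[full["land_use"] == scenario.land_use]
    children = np.random.SeedSequence(base_seed).spawn(n_replicates)
    rs = np.empty(n_replicates)
    for k, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        config = replace(scenario.config, seed=seed)
        traits = generate_traits(metadata, None, config)
        rs[k] = pearson_with_p(traits[trait_a], traits[trait_b]).r
    return rs


def simulate_scenario(name: str, seed: int = 0) -> SyntheticDataset:
    """Generate the full dataset for one scenario's land-use group.

    The crossed design is enumerated in full (48 samples by default), then
    restricted to the scenario's land-use level (24 samples), matching an
    analysis that builds one network per land use.
    """
    scenario = load_scenario(name, seed=seed)
    full = generate_design(scenario.design)
    metadata = full[full["land_use"] == scenario.land_use]
    table = generate_counts(metadata, scenario.config)
    traits = generate_traits(metadata, table, scenario.config)
    return SyntheticDataset(metadata, table, traits, scenario.config)
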