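"""Synthetic data generator emulating the chorus-frog brain RNA-seq design.

Generates NB-distributed count matrices for the four geography x sex
groups (unbalanced n = 5, 3, 4, 4), with planted geography- and
sex-associated fold changes (more geography-DE than sex-DE, more
female-geography-DE than male), latent-factor co-expression modules
optionally tied to a trait, candidate-gene annotation text and a
pathway-to-module table with planted synaptic concentration.  A truth
table records every planted feature for parameter-recovery testing.

All randomness flows from one integer seed; per-component child
generators are derived with fixed offsets so regenerating a single
output is reproducible.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import CountMatrix, SampleTable

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_annotations",
    "generate_pathway_table",
    "simulate_all",
]

# fixed per-component seed offsets (one logical RNG stream)
_OFFSETS = {"libs": 1, "baseline": 2, "de": 3, "modules": 4,
            "counts": 5, "annotations": 6, "pathways": 7}

DEFAULT_GROUP_SIZES = {
    ("allopatric", "female"): 5,
    ("allopatric", "male"): 3,
    ("sympatric", "female"): 4,
    ("sympatric", "male"): 4,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([_OFFSETS[component], int(seed)])


@dataclasses.dataclass
class SimulationConfig:
    """Stated world of the generator; defaults emulate the study design.

    Library sizes are desk-scale (2e6 expected counts, lognormal with
    CV 0.25) rather than the study's tens of millions of read pairs;
    scale does not change the statistics exercised.  Dispersion follows
    phi_g = bcv0^2 + bcv_trend / mu_g.  Module structure is a single
    latent factor per module, z_s = a * trait_s + sqrt(1-a^2) * noise,
    added to log2 abundance with a fixed gene loading.
    """

    n_genes: int = 2000
    group_sizes: Mapping = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    lib_size_mean: float = 2e6
    lib_size_cv: float = 0.25
    baseline_logmean_mean: float = 3.0
    baseline_logmean_sd: float = 2.0
    bcv0: float = 0.4
    bcv_trend: float = 2.0
    frac_de_geo_female: float = 0.065
    frac_de_geo_male: float = 0.01
    frac_de_geo_both: float = 0.02
    frac_de_sex: float = 0.015
    lfc_magnitude: float = 2.0
    lfc_sd: float = 0.0
    cross_sex_attenuation: float = 0.5
    n_modules: int = 12
    module_size: int = 35
    module_traits: Sequence = ("geography", "geography", "geography", "sex")
    module_trait_strength: float = 0.75
    module_loading: float = 0.8
    frac_candidate: float = 0.05
    decoy_fraction: float = 0.02
    pathway_plan: Mapping | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least one sample")
        fracs = {
            "frac_de_geo_female": self.frac_de_geo_female,
            "frac_de_geo_male": self.frac_de_geo_male,
            "frac_de_geo_both": self.frac_de_geo_both,
            "frac_de_sex": self.frac_de_sex,
            "frac_candidate": self.frac_candidate,
            "decoy_fraction": self.decoy_fraction,
        }
        for k, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must lie in [0, 1]")
        de_sum = (self.frac_de_geo_female + self.frac_de_geo_male
                  + self.frac_de_geo_both + self.frac_de_sex)
        if de_sum > 1.0:
            raise ValueError("DE fractions sum to more than 1")
        groups = set(self.group_sizes)
        needed = []
        if self.frac_de_geo_female > 0 or self.frac_de_geo_both > 0:
            needed += [("allopatric", "female"), ("sympatric", "female")]
        if self.frac_de_geo_male > 0 or self.frac_de_geo_both > 0:
            needed += [("allopatric", "male"), ("sympatric", "male")]
        missing = [g for g in needed if g not in groups]
        if missing:
            raise ValueError(f"DE fraction names empty group(s): {missing}")
        if len(tuple(self.module_traits)) < self.n_modules:
            self.module_traits = tuple(self.module_traits) + (
                (None,) * (self.n_modules - len(tuple(self.module_traits))))
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit in n_genes")

    def module_names(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_modules)]


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    abbrev = {("allopatric", "female"): "AF", ("allopatric", "male"): "AM",
              ("sympatric", "female"): "SF", ("sympatric", "male"): "SM"}
    for (geo, sex), n in config.group_sizes.items():
        tag = abbrev.get((geo, sex), f"{geo[:1]}{sex[:1]}".upper())
        for i in range(n):
            rows.append((f"{tag}{i + 1}", geo, sex))
    df = pd.DataFrame(rows, columns=["sample_id", "geography", "sex"])
    return df.set_index("sample_id")


def generate_dataset(config: SimulationConfig):
    """Draw (CountMatrix, SampleTable, TruthTable) from the stated world.

    Counts are gamma-Poisson (NB) draws with mean
    ``mu_gs = libsize_s * q_gs / sum_g q_gs`` where
    ``log2 q_gs = baseline_g + planted lfc terms + loading * z_s``.
    The truth table records DE flags, true log2 fold changes, module
    membership and candidate status per gene.
    """
    meta = _sample_frame(config)
    samples = SampleTable(meta)
    n = len(meta)
    G = config.n_genes
    genes = [f"g{i:05d}" for i in range(G)]

    lib_rng = _rng(config.seed, "libs")
    cv = config.lib_size_cv
    sigma2 = np.log1p(cv * cv)
    lib = lib_rng.lognormal(np.log(config.lib_size_mean) - sigma2 / 2.0,
                            np.sqrt(sigma2), size=n)

    base_rng = _rng(config.seed, "baseline")
    baseline = base_rng.normal(config.baseline_logmean_mean,
                               config.baseline_logmean_sd, size=G)

    # planted DE effects: disjoint gene blocks drawn from a shuffled order
    de_rng = _rng(config.seed, "de")
    order = de_rng.permutation(G)
    n_both = int(round(config.frac_de_geo_both * G))
    n_gf = int(round(config.frac_de_geo_female * G))
    n_gm = int(round(config.frac_de_geo_male * G))
    n_sex = int(round(config.frac_de_sex * G))
    cut = np.cumsum([n_both, n_gf, n_gm, n_sex])
    idx_both = order[:cut[0]]
    idx_gf = order[cut[0]:cut[1]]
    idx_gm = order[cut[1]:cut[2]]
    idx_sex = order[cut[2]:cut[3]]

    def draw_lfc(rng, size):
        mag = np.full(size, config.lfc_magnitude)
        if config.lfc_sd > 0:
            mag = np.abs(rng.normal(config.lfc_magnitude, config.lfc_sd, size))
        return mag * rng.choice([-1.0, 1.0], size=size)

    # Sex-biased geography effects act in both sexes with the full
    # magnitude in the biased sex and an attenuated magnitude in the
    # other, matching the observed pattern of largely shared but
    # sex-modulated expression divergence.
    att = config.cross_sex_attenuation
    lfc_geo_f = np.zeros(G)  # geography lfc expressed in females
    lfc_geo_m = np.zeros(G)  # geography lfc expressed in males
    lfc_both = draw_lfc(de_rng, n_both)
    lfc_f = draw_lfc(de_rng, n_gf)
    lfc_m = draw_lfc(de_rng, n_gm)
    lfc_geo_f[idx_both] = lfc_both
    lfc_geo_m[idx_both] = lfc_both
    lfc_geo_f[idx_gf] = lfc_f
    lfc_geo_m[idx_gf] = att * lfc_f
    lfc_geo_f[idx_gm] = att * lfc_m
    lfc_geo_m[idx_gm] = lfc_m
    true_lfc_geo = np.where(np.abs(lfc_geo_f) >= np.abs(lfc_geo_m),
                            lfc_geo_f, lfc_geo_m)
    true_lfc_sex = np.zeros(G)
    true_lfc_sex[idx_sex] = draw_lfc(de_rng, n_sex)

    is_sym = (meta["geography"] == "sympatric").to_numpy()
    is_fem = (meta["sex"] == "female").to_numpy()

    log2q = np.tile(baseline[:, None], (1, n))
    log2q[:, is_sym & is_fem] += lfc_geo_f[:, None]
    log2q[:, is_sym & ~is_fem] += lfc_geo_m[:, None]
    log2q[:, is_fem] += true_lfc_sex[:, None]

    # planted modules on genes free of planted DE
    mod_rng = _rng(config.seed, "modules")
    free = order[cut[3]:]
    true_module = np.array([""] * G, dtype=object)
    a = config.module_trait_strength
    for m, trait in zip(range(config.n_modules), config.module_traits):
        members = free[m * config.module_size:(m + 1) * config.module_size]
        true_module[members] = f"M{m + 1}"
        if trait == "geography":
            code = np.where(is_sym, 1.0, -1.0)
        elif trait == "sex":
            code = np.where(is_fem, 1.0, -1.0)
        elif trait is None:
            code = np.zeros(n)
        else:
            raise ValueError(f"unknown module trait {trait!r}")
        noise = mod_rng.standard_normal(n)
        if trait is None:
            z = noise
        else:
            z = a * code + np.sqrt(1.0 - a * a) * noise
        log2q[members] += config.module_loading * z[None, :]

    # candidates drawn uniformly (independent of DE status, as in the study)
    n_cand = int(round(config.frac_candidate * G))
    cand_idx = de_rng.choice(G, size=n_cand, replace=False) if n_cand else np.array([], int)
    is_candidate = np.zeros(G, dtype=bool)
    is_candidate[cand_idx] = True

    q = 2.0 ** log2q
    p = q / q.sum(axis=0, keepdims=True)
    mu = p * lib[None, :]
    mu_bar = np.maximum(mu.mean(axis=1), 1e-8)
    phi = config.bcv0 ** 2 + config.bcv_trend / mu_bar

    cnt_rng = _rng(config.seed, "counts")
    counts = np.empty((G, n), dtype=np.int64)
    pos = phi > 0
    if pos.any():
        shape = 1.0 / phi[pos]
        lam = cnt_rng.gamma(shape[:, None], phi[pos][:, None] * mu[pos])
        counts[pos] = cnt_rng.poisson(lam)
    if (~pos).any():
        counts[~pos] = cnt_rng.poisson(mu[~pos])

    count_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    truth = pd.DataFrame({
        "is_de_geo_female": lfc_geo_f != 0,
        "is_de_geo_male": lfc_geo_m != 0,
        "is_de_sex": np.isin(np.arange(G), idx_sex),
        "true_lfc_geo": true_lfc_geo,
        "true_lfc_geo_female": lfc_geo_f,
        "true_lfc_geo_male": lfc_geo_m,
        "true_lfc_sex": true_lfc_sex,
        "true_module": true_module,
        "is_candidate": is_candidate,
    }, index=genes)
    return CountMatrix(count_df), samples, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_NEUTRAL_TERMS = [
    "ribosomal protein L7", "elongation factor 1-alpha",
    "heat shock protein HSP70", "collagen alpha-1 chain",
    "hemoglobin subunit beta", "myosin light chain 3", "histone H2B type 1",
    "ubiquitin-conjugating enzyme E2", "carbonic anhydrase 2",
    "lactate dehydrogenase A", "glyceraldehyde-3-phosphate dehydrogenase",
    "ferritin heavy chain", "alpha-enolase", "tubulin beta chain",
]


def generate_annotations(truth: pd.DataFrame, rules=None,
                         decoy_fraction: float = 0.02,
                         seed: int = 0) -> pd.DataFrame:
    """Free-text Trinotate-style annotations with planted candidates.

    Every candidate gene receives a string containing a keyword from one
    rule; a ``decoy_fraction`` of non-candidates receive a string that
    contains a broad keyword but also triggers that rule's exclusion
    pattern, so a correct matcher rejects them.  Remaining genes get
    neutral filler terms free of any keyword.
    """
    from .candidates import default_rules

    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("keyword rule table is empty")
    rng = _rng(seed, "annotations")
    with_excl = [r for r in rules if r.exclude_patterns]
    ann = {}
    loc = 100000
    for gene, row in truth.iterrows():
        terms = [str(rng.choice(_NEUTRAL_TERMS))]
        if row["is_candidate"]:
            rule = rules[int(rng.integers(len(rules)))]
            text = f"{rule.family_name} ({rule.keyword} family protein)"
            if rule.include_patterns:
                # satisfy the rule's own refinement with its first literal
                text += f", {rule.include_patterns[0]}"
            terms.append(text)
        elif with_excl and rng.random() < decoy_fraction:
            rule = with_excl[int(rng.integers(len(with_excl)))]
            bad = rule.exclude_patterns[0]
            terms.append(f"{rule.keyword}-like protein, {bad}")
        else:
            loc += 1
            terms.append(f"uncharacterized protein LOC{loc}")
        ann[gene] = "|".join(terms)
    return pd.DataFrame({"annotation": pd.Series(ann)}).rename_axis("gene_id")


# ---------------------------------------------------------------------------
# pathway table
# ---------------------------------------------------------------------------

_SYNAPTIC_NAMES = [
    "synaptic vesicle cycle", "regulation of synapse assembly",
    "chemical synaptic transmission", "synaptic membrane adhesion",
    "presynaptic active zone organization", "postsynaptic density assembly",
    "neurotransmitter secretion", "neuron projection guidance",
    "neuromuscular junction development", "neural crest cell migration",
    "neuroblast proliferation", "neurotransmitter receptor transport",
    "synaptonemal complex assembly", "neurogenesis",
    "regulation of neuronal synaptic plasticity",
]

_NONSYNAPTIC_NAMES = [
    "citric acid cycle", "ribosome biogenesis", "DNA replication initiation",
    "fatty acid beta-oxidation", "transcription factor binding",
    "proteasome assembly", "mRNA splicing via spliceosome",
    "oxidative phosphorylation", "cell cycle checkpoint", "glycolysis",
    "tRNA aminoacylation", "protein folding", "lipid droplet organization",
    "histone modification", "vesicle coating", "ion homeostasis",
    "actin filament organization", "chromatin remodeling",
    "RNA polymerase II initiation", "telomere maintenance",
]

_SYNAPTIC_ANCESTORS = [
    "nervous system development; chemical synaptic transmission",
    "signaling; neurotransmitter transport",
    "cell communication; synaptic signaling",
]
_NEUTRAL_ANCESTORS = [
    "metabolic process; small molecule metabolism",
    "cellular process; organelle organization",
    "biological regulation; response to stimulus",
]


def default_pathway_plan(config: SimulationConfig) -> dict:
    """Per-module pathway counts with synaptic fractions tied to traits.

    Geography-associated modules are planted synaptic-rich (12 of 20);
    other modules get background levels (2 of 20), emulating the
    concentration pattern reported for the geography modules.
    """
    plan = {}
    for name, trait in zip(config.module_names(), config.module_traits):
        plan[name] = (20, 12 if trait == "geography" else 2)
    return plan


def generate_pathway_table(module_labels, pathway_plan: Mapping,
                           seed: int = 0) -> pd.DataFrame:
    """Pathway-to-module table with planted synaptic flags.

    Each row carries a pathway id, module, name text and ancestor/child
    term text; synaptic rows contain a "synap"/"neuro"/"neura" substring
    in one of the two text fields, split between them at random.  Counts
    per module follow the plan exactly.
    """
    module_labels = list(module_labels)
    unknown = [m for m in pathway_plan if m not in module_labels]
    if unknown:
        raise ValueError(f"pathway plan references unknown module(s): {unknown}")
    rng = _rng(seed, "pathways")
    rows = []
    pid = 0
    for module in module_labels:
        if module not in pathway_plan:
            continue
        n_pw, n_syn = pathway_plan[module]
        if isinstance(n_syn, float) and 0 <= n_syn <= 1:
            n_syn = int(round(n_syn * n_pw))
        if n_syn > n_pw:
            raise ValueError(f"module {module}: more synaptic than total pathways")
        for i in range(n_pw):
            pid += 1
            synaptic = i < n_syn
            if synaptic:
                if rng.random() < 0.5:
                    name = str(rng.choice(_SYNAPTIC_NAMES))
                    anc = str(rng.choice(_NEUTRAL_ANCESTORS))
                else:
                    name = str(rng.choice(_NONSYNAPTIC_NAMES))
                    anc = str(rng.choice(_SYNAPTIC_ANCESTORS))
            else:
                name = str(rng.choice(_NONSYNAPTIC_NAMES))
                anc = str(rng.choice(_NEUTRAL_ANCESTORS))
            rows.append((f"P{pid:04d}", module, name, anc))
    df = pd.DataFrame(rows, columns=["pathway_id", "module", "name_text",
                                     "ancestor_child_text"])
    return df.set_index("pathway_id")


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticDataset:
    config: SimulationConfig
    counts: CountMatrix
    samples: SampleTable
    truth: pd.DataFrame
    annotations: pd.DataFrame
    pathways: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.counts.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
        self.samples.table.rename_axis("sample_id").to_csv(out / "samples.tsv", sep="\t")
        self.annotations.to_csv(out / "annotations.tsv", sep="\t")
        self.pathways.to_csv(out / "pathways.tsv", sep="\t")
        self.truth.rename_axis("gene_id").to_csv(out / "truth.tsv", sep="\t")


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate counts, metadata, annotations and pathway table in one call."""
    counts, samples, truth = generate_dataset(config)
    ann = generate_annotations(truth, decoy_fraction=config.decoy_fraction,
                               seed=config.seed)
    plan = config.pathway_plan or default_pathway_plan(config)
    pathways = generate_pathway_table(config.module_names(), plan, config.seed)
    return SyntheticDataset(config, counts, samples, truth, ann, pathways)
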