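"""Forward-time simulator of epigenetic drift with purifying selection.

The generative model behind every synthetic fixture in this package:

* Each cell carries a binary methylation state (0/1) at every CpG site.
* Per generation, every site of every cell flips with probability
  ``error_rate`` (replication-error drift).
* Cell fitness is w = exp(-s * h), where h is the number of *essential*
  sites whose state differs from the optimum configuration; non-essential
  sites are neutral. The next generation is drawn Wright–Fisher style:
  constant population size, parents sampled proportional to fitness.
* A demethylating shock (5-azacitidine-like) turns each methylated site of
  each cell off with probability ``shock_prob``.
* An array measurement of a population reports, per site, the fraction of
  methylated cells plus Gaussian noise (sd ``measurement_noise_sd``),
  truncated to [0, 1] — the simulated beta value.

With s > 0, drift accumulates freely at non-essential sites while selection
holds essential sites near the optimum, so essential genes end up with
smaller pairwise differences between replicate populations — the
conservation signal the analysis pipeline is designed to detect. The
``generate_scenario`` entry point packages four study designs (clonal drift,
crypts within individuals, shock/recovery, drug panel) as beta matrices plus
sample sheets, annotation, gene-effect and drug-response tables, and a
ground-truth gene table, all in the formats the I/O module reads.

All randomness flows from ``SimConfig.seed`` through spawned child streams,
so identical config means bit-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as eio
from . import __version__

__all__ = [
    "SimConfig",
    "CellPopulation",
    "ScenarioData",
    "init_population",
    "step_generation",
    "evolve",
    "apply_shock",
    "measure_beta",
    "cross_population_pwd",
    "replicate_pair_divergence",
    "generate_scenario",
    "write_scenario",
    "SCENARIOS",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the drift + selection model and of the study designs."""

    # population / genome
    n_cells: int = 200
    n_genes: int = 100
    cpgs_per_gene: int = 5
    essential_fraction: float = 0.2
    # dynamics
    error_rate: float = 0.002          # per-site per-generation flip probability
    selection: float = 2.0             # fitness penalty per deviant essential site
    generations: int = 500
    optimum_state: int = 1             # target state at essential sites
    shock_prob: float = 0.5            # per-methylated-site demethylation probability
    # measurement
    measurement_noise_sd: float = 0.005
    n_replicates: int = 3
    seed: int = 1
    # time bookkeeping: culture at ~1 division/day, 25 divisions/month
    months_per_generation: float = 0.04
    # scenario designs
    clonal_checkpoints: tuple[int, ...] = (62, 350, 500)   # ~2.5 / 14 / 20 months
    n_individuals: int = 8
    units_per_individual: int = 4
    burn_in: int = 100                                      # pre-shock optimization
    recovery_times: tuple[int, ...] = (5, 15, 30, 50, 68)   # days post shock
    # drug panel
    n_lines: int = 30
    n_target_genes: int = 5
    drug_effect_size: float = 0.5
    line_generations: tuple[int, int] = (30, 230)
    # synthetic gene-effect table
    n_effect_lines: int = 9
    effect_essential_mean: float = -0.6
    effect_non_essential_mean: float = -0.1
    effect_jitter_sd: float = 0.05

    def __post_init__(self):
        for name in ("essential_fraction", "error_rate", "shock_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.selection < 0 or self.measurement_noise_sd < 0:
            raise ValueError("selection and measurement_noise_sd must be >= 0")
        if self.optimum_state not in (0, 1):
            raise ValueError("optimum_state must be 0 or 1")

    # -- derived genome layout -------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.n_genes * self.cpgs_per_gene

    @property
    def n_essential_genes(self) -> int:
        return int(round(self.n_genes * self.essential_fraction))

    def gene_names(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(1, self.n_genes + 1)]

    def site_ids(self) -> list[str]:
        return [f"cg{i:06d}" for i in range(1, self.n_sites + 1)]

    def essential_sites(self) -> np.ndarray:
        """Site indices of essential genes (the first ``n_essential_genes``)."""
        return np.arange(self.n_essential_genes * self.cpgs_per_gene)

    def annotation(self) -> pd.DataFrame:
        genes = np.repeat(self.gene_names(), self.cpgs_per_gene)
        return pd.DataFrame({"cpg_id": self.site_ids(), "gene": genes})

    def ground_truth(self) -> pd.DataFrame:
        ess = np.zeros(self.n_genes, dtype=bool)
        ess[: self.n_essential_genes] = True
        return pd.DataFrame(
            {"essential": ess}, index=pd.Index(self.gene_names(), name="gene")
        )

    @classmethod
    def drug_panel(cls, seed: int = 1, **overrides) -> "SimConfig":
        """Panel-scale defaults: many lines, small per-line populations.

        A 30-line panel at the full clonal-drift scale would dominate runtime
        for no statistical gain, so the panel uses smaller populations and
        genomes; line divergence times are spread over ``line_generations``
        so conservation genuinely varies across lines.
        """
        params = dict(n_cells=60, n_genes=30, cpgs_per_gene=3, seed=seed)
        params.update(overrides)
        return cls(**params)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CellPopulation:
    """Binary per-cell methylation states; rows = cells, columns = sites."""

    states: np.ndarray  # uint8, shape (n_cells, n_sites)
    generation: int = 0

    def copy(self) -> "CellPopulation":
        return CellPopulation(self.states.copy(), self.generation)

    @property
    def site_fraction(self) -> np.ndarray:
        """Per-site fraction of methylated cells (the noiseless beta)."""
        return self.states.mean(axis=0)


# ---------------------------------------------------------------------------
# core dynamics

def init_population(config: SimConfig, rng: np.random.Generator) -> CellPopulation:
    """Clonal founding population.

    One random founder epigenome is drawn (each non-essential site Bernoulli
    1/2), essential sites are set to the optimum state, and every cell is an
    identical copy — so between-replicate PWD at generation 0 is exactly 0
    when measured without noise.
    """
    founder = rng.integers(0, 2, size=config.n_sites, dtype=np.uint8)
    founder[config.essential_sites()] = config.optimum_state
    states = np.broadcast_to(founder, (config.n_cells, config.n_sites)).copy()
    return CellPopulation(states, generation=0)


def step_generation(
    pop: CellPopulation, config: SimConfig, rng: np.random.Generator
) -> CellPopulation:
    """One Wright–Fisher generation: mutation, selection, reproduction."""
    flips = (rng.random(pop.states.shape) < config.error_rate).astype(np.uint8)
    states = pop.states ^ flips
    n = states.shape[0]
    if config.selection > 0 and config.n_essential_genes > 0:
        h = np.count_nonzero(
            states[:, config.essential_sites()] != config.optimum_state, axis=1
        )
        # subtract min(h) before exponentiating: same normalized weights,
        # no underflow even for large s*h
        w = np.exp(-config.selection * (h - h.min()))
        parents = rng.choice(n, size=n, p=w / w.sum())
    else:
        parents = rng.integers(0, n, size=n)
    return CellPopulation(states[parents], generation=pop.generation + 1)


def evolve(
    pop: CellPopulation,
    config: SimConfig,
    rng: np.random.Generator,
    generations: int,
) -> CellPopulation:
    """Advance ``generations`` steps, returning the final population."""
    for _ in range(generations):
        pop = step_generation(pop, config, rng)
    return pop


def apply_shock(
    pop: CellPopulation, config: SimConfig, rng: np.random.Generator
) -> CellPopulation:
    """Demethylating shock: each methylated site switches off w.p. ``shock_prob``."""
    hit = (pop.states == 1) & (rng.random(pop.states.shape) < config.shock_prob)
    states = pop.states.copy()
    states[hit] = 0
    return CellPopulation(states, pop.generation)


def measure_beta(
    pop: CellPopulation,
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str,
) -> pd.Series:
    """Array measurement: per-site methylated fraction + noise, in [0, 1]."""
    beta = pop.site_fraction.astype(float)
    if config.measurement_noise_sd > 0:
        beta = beta + rng.normal(0.0, config.measurement_noise_sd, beta.shape)
    beta = np.clip(beta, 0.0, 1.0)
    return pd.Series(beta, index=pd.Index(config.site_ids(), name="cpg_id"), name=sample_id)


def cross_population_pwd(pop_a: CellPopulation, pop_b: CellPopulation) -> np.ndarray:
    """Per-site mean pairwise difference between cells of two populations.

    For binary states |a - b| is a mismatch indicator, so the all-cross-pairs
    PWD reduces to f_a + f_b - 2 f_a f_b with f the per-site methylated
    fractions. For two populations that were clonal at their split t
    generations ago, its expectation is exactly
    ½(1 − (1 − 2ε)^(2t)) at every site (each cross pair of lineages is
    separated by exactly 2t flip opportunities), independent of population
    size and of selection-free resampling.
    """
    fa = pop_a.site_fraction
    fb = pop_b.site_fraction
    return fa + fb - 2.0 * fa * fb


def neutral_divergence_expectation(error_rate: float, t: int) -> float:
    """Closed-form expected cross-population PWD after a clonal split."""
    return 0.5 * (1.0 - (1.0 - 2.0 * error_rate) ** (2 * t))


def replicate_pair_divergence(
    config: SimConfig, times: Sequence[int]
) -> dict[int, np.ndarray]:
    """Per-site cross-replicate PWD at the requested generation counts.

    Two populations are split from one clonal founder and evolved
    independently; at each time in ``times`` the per-site cross-population
    PWD is recorded. Used to check the simulator's drift dynamics against
    the neutral closed form.
    """
    seqs = np.random.SeedSequence(config.seed).spawn(3)
    founder = init_population(config, np.random.default_rng(seqs[0]))
    pops = [founder.copy(), founder.copy()]
    rngs = [np.random.default_rng(s) for s in seqs[1:]]
    out: dict[int, np.ndarray] = {}
    for t in sorted(set(int(t) for t in times)):
        for i in (0, 1):
            pops[i] = evolve(pops[i], config, rngs[i], t - pops[i].generation)
        out[t] = cross_population_pwd(pops[0], pops[1])
    return out


# ---------------------------------------------------------------------------
# scenario generation

@dataclass
class ScenarioData:
    """Everything a pipeline stage needs, in the shared data model."""

    name: str
    config: SimConfig
    beta: pd.DataFrame
    sheet: pd.DataFrame
    annotation: pd.DataFrame
    gene_effect: pd.DataFrame
    ground_truth: pd.DataFrame
    drug_response: pd.DataFrame | None = None


def _gene_effect_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic DepMap-like gene-effect matrix consistent with ground truth.

    Essential genes score around -0.6, non-essential around -0.1, with
    Gaussian jitter per (line, gene); the -0.4 call threshold separates the
    classes with negligible error at the default jitter.
    """
    truth = config.ground_truth()["essential"].to_numpy()
    means = np.where(
        truth, config.effect_essential_mean, config.effect_non_essential_mean
    )
    scores = means + rng.normal(
        0.0, config.effect_jitter_sd, size=(config.n_effect_lines, config.n_genes)
    )
    lines = [f"SIMLINE{i:02d}" for i in range(1, config.n_effect_lines + 1)]
    return pd.DataFrame(
        scores, index=pd.Index(lines, name="cell_line"), columns=config.gene_names()
    )


def _assemble(name, config, columns, sheet_rows, rng_effect, drug=None) -> ScenarioData:
    beta = pd.concat(columns, axis=1)
    sheet = pd.DataFrame.from_records(
        sheet_rows,
        columns=["sample_id", "group", "tissue", "time", "time_unit", "condition"],
    )
    return ScenarioData(
        name=name,
        config=config,
        beta=beta,
        sheet=sheet,
        annotation=config.annotation(),
        gene_effect=_gene_effect_table(config, rng_effect),
        ground_truth=config.ground_truth(),
        drug_response=drug,
    )


def _clonal_drift(config: SimConfig) -> ScenarioData:
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_replicates + 2)
    founder = init_population(config, np.random.default_rng(seqs[0]))
    checkpoints = sorted(set(config.clonal_checkpoints))
    columns, rows = [], []
    for r in range(config.n_replicates):
        rng = np.random.default_rng(seqs[1 + r])
        pop = founder.copy()
        for g in checkpoints:
            pop = evolve(pop, config, rng, g - pop.generation)
            sid = f"rep{r + 1}_g{g}"
            columns.append(measure_beta(pop, config, rng, sid))
            rows.append(
                (sid, f"t{g}", "culture", g * config.months_per_generation, "months", "control")
            )
    return _assemble("clonal_drift", config, columns, rows,
                     np.random.default_rng(seqs[-1]))


def _crypts(config: SimConfig) -> ScenarioData:
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_individuals + 1)
    anc_gens = config.generations // 2
    columns, rows = [], []
    for i in range(config.n_individuals):
        child = seqs[i].spawn(config.units_per_individual + 2)
        rng0 = np.random.default_rng(child[0])
        ancestor = evolve(init_population(config, rng0), config, rng0, anc_gens)
        for j in range(config.units_per_individual):
            rng = np.random.default_rng(child[1 + j])
            crypt = evolve(ancestor.copy(), config, rng, config.generations - anc_gens)
            sid = f"ind{i + 1}_crypt{j + 1}"
            columns.append(measure_beta(crypt, config, rng, sid))
            rows.append(
                (sid, f"ind{i + 1}", "colon",
                 config.generations * config.months_per_generation, "months", "control")
            )
    return _assemble("crypts", config, columns, rows, np.random.default_rng(seqs[-1]))


def _aza_recovery(config: SimConfig) -> ScenarioData:
    seqs = np.random.SeedSequence(config.seed).spawn(4)
    rng0 = np.random.default_rng(seqs[0])
    base = evolve(init_population(config, rng0), config, rng0, config.burn_in)
    control = base.copy()
    rng_ctrl = np.random.default_rng(seqs[1])
    rng_trt = np.random.default_rng(seqs[2])
    treated = apply_shock(base.copy(), config, rng_trt)
    columns, rows = [], []
    for day in sorted(set(config.recovery_times)):
        steps = day - (control.generation - base.generation)
        control = evolve(control, config, rng_ctrl, steps)
        treated = evolve(treated, config, rng_trt, steps)
        for label, pop, rng, cond in (
            ("ctrl", control, rng_ctrl, "control"),
            ("aza", treated, rng_trt, "aza"),
        ):
            sid = f"{label}_d{day}"
            columns.append(measure_beta(pop, config, rng, sid))
            rows.append((sid, "line1", "culture", day, "days", cond))
    return _assemble("aza_recovery", config, columns, rows, np.random.default_rng(seqs[-1]))


def _drug_panel(config: SimConfig) -> ScenarioData:
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_lines + 2)
    lo, hi = config.line_generations
    t_lines = np.linspace(lo, hi, config.n_lines).round().astype(int)
    genes = config.gene_names()
    truth = config.ground_truth()
    non_essential = [g for g in genes if not truth.loc[g, "essential"]]
    targets = non_essential[: config.n_target_genes]
    if len(targets) < config.n_target_genes:
        raise ValueError("not enough non-essential genes for the requested drug targets")

    columns, rows = [], []
    latent = np.zeros((config.n_lines, len(targets)))  # true target divergence/line
    gene_of_site = np.repeat(genes, config.cpgs_per_gene)
    for l, t_l in enumerate(t_lines):
        child = seqs[l].spawn(3)
        founder = init_population(config, np.random.default_rng(child[0]))
        reps = []
        for r in (0, 1):
            rng = np.random.default_rng(child[1 + r])
            pop = evolve(founder.copy(), config, rng, int(t_l))
            reps.append(pop)
            sid = f"line{l + 1:02d}_rep{r + 1}"
            columns.append(measure_beta(pop, config, rng, sid))
            rows.append(
                (sid, f"line{l + 1:02d}", "culture",
                 t_l * config.months_per_generation, "months", "control")
            )
        site_div = cross_population_pwd(reps[0], reps[1])
        for gi, g in enumerate(targets):
            latent[l, gi] = site_div[gene_of_site == g].mean()

    # sensitivity scores: planted correlation with target conservation.
    # Both axes oriented negative-is-more (conserved / sensitive), so the
    # planted Pearson r equals +effect_size in expectation.
    rng_drug = np.random.default_rng(seqs[-2])
    effect = config.drug_effect_size
    line_ids = [f"line{l + 1:02d}" for l in range(config.n_lines)]
    drug_rows = []
    std = latent.std(axis=0, ddof=1)
    zlat = (latent - latent.mean(axis=0)) / np.where(std > 0, std, 1.0)
    drug_specs = [(f"DRUG_{g}", [g]) for g in targets]
    drug_specs.append(("DRUG_DUAL", targets[:2]))  # one multi-target drug
    for drug, tgts in drug_specs:
        for g in tgts:
            gi = targets.index(g)
            noise = rng_drug.normal(0.0, 1.0, config.n_lines)
            score = effect * zlat[:, gi] + np.sqrt(max(1.0 - effect**2, 0.0)) * noise
            for l, line in enumerate(line_ids):
                drug_rows.append((line, drug, g, score[l]))
    drug_df = pd.DataFrame(drug_rows, columns=["cell_line", "drug", "target", "score"])
    data = _assemble("drug_panel", config, columns, rows,
                     np.random.default_rng(seqs[-1]), drug=drug_df)
    data.ground_truth = data.ground_truth.copy()
    data.ground_truth["drug_target"] = data.ground_truth.index.isin(targets)
    data.ground_truth.attrs["drug_effect_size"] = effect
    return data


SCENARIOS: Mapping[str, callable] = {
    "clonal_drift": _clonal_drift,
    "crypts": _crypts,
    "aza_recovery": _aza_recovery,
    "drug_panel": _drug_panel,
}


def generate_scenario(name: str, config: SimConfig | None = None) -> ScenarioData:
    """Generate one of the four study designs; see the module docstring."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    if config is None:
        config = SimConfig.drug_panel() if name == "drug_panel" else SimConfig()
    return SCENARIOS[name](config)


def write_scenario(data: ScenarioData, outdir) -> dict:
    """Write all scenario tables in the formats the I/O module reads.

    Emits beta_matrix.tsv, sample_sheet.csv, annotation.tsv,
    gene_effect.csv, drug_response.csv (when present), ground_truth.tsv and
    a manifest.json with the config hash and seed. Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.beta.to_csv(outdir / "beta_matrix.tsv", sep="\t")
    data.sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    data.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    # DepMap-style labels so the reader's "SYMBOL (id)" parsing is exercised
    effect = data.gene_effect.copy()
    effect.columns = [f"{g} ({i + 1})" for i, g in enumerate(effect.columns)]
    effect.to_csv(outdir / "gene_effect.csv")
    if data.drug_response is not None:
        data.drug_response.to_csv(outdir / "drug_response.csv", index=False)
    data.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
    manifest = {
        "tool": f"epiconserve {__version__}",
        "scenario": data.name,
        "seed": data.config.seed,
        "config_hash": data.config.hash(),
        "config": dataclasses.asdict(data.config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
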