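"""Synthetic populations, genotypes, replicated PCRs, and qPCR plates.

The generator emulates the statistical structure a noninvasive
microsatellite study assumes: several populations (species or lineages)
with Dirichlet-distributed allele frequencies and planted private alleles;
individuals drawn under Hardy-Weinberg with optional inbreeding; per-locus
replicated PCR observations corrupted by amplification failure, allelic
dropout, and stutter-like false alleles; and qPCR plates whose Cq values
follow a log-linear standard curve with optional per-sample inhibition
shifts.

The observation model is deliberately the one the downstream estimators
target: dropout acts per heterozygous replicate (one allele, chosen
uniformly, is lost with probability ``ado_prob``), a false allele is one
repeat unit away from a true allele, and failure empties the replicate.
Under the reference-scored error-rate definitions this makes parameter
recovery exact in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .identity import KIWI_SEX_MODEL, SexMarkerModel
from .panel import PanelDefinition


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    species: str
    lineage: str | None = None


@dataclass
class PopulationModel:
    """Per-population, per-locus allele frequencies over integer sizes."""

    panel: PanelDefinition
    populations: list[PopulationSpec]
    #: population -> locus -> {allele size: frequency}
    allele_freqs: dict[str, dict[str, dict[int, float]]]
    inbreeding_f: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for pop, loci in self.allele_freqs.items():
            for locus, freqs in loci.items():
                total = sum(freqs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{pop}/{locus}: frequencies sum to {total}")
                if any(f < 0 for f in freqs.values()):
                    raise ValueError(f"{pop}/{locus}: negative frequency")
        for pop, f in self.inbreeding_f.items():
            if not 0 <= f <= 1:
                raise ValueError(f"{pop}: inbreeding f must be in [0, 1]")

    def support(self, pop: str, locus: str) -> set[int]:
        return {a for a, f in self.allele_freqs[pop][locus].items() if f > 0}


@dataclass(frozen=True)
class ErrorModel:
    """Per-replicate PCR error process.

    fail_prob : amplification failure probability (replicate is empty).
    ado_prob : probability a heterozygous replicate loses one uniformly
        chosen allele (a false homozygote results).
    fa_prob : probability a positive replicate gains a stutter artifact one
        repeat unit away from a true allele, clipped to the locus range.
    replicates : PCR replicates per sample x locus (the multi-tube count).
    """

    fail_prob: float = 0.0
    ado_prob: float = 0.0
    fa_prob: float = 0.0
    replicates: int = 4

    def __post_init__(self) -> None:
        for name in ("fail_prob", "ado_prob", "fa_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_populations(
    panel: PanelDefinition,
    populations: list[PopulationSpec],
    n_alleles: int = 6,
    concentration: float = 1.0,
    private_allele_plan: dict[str, list[str]] | None = None,
    inbreeding_f: dict[str, float] | None = None,
    seed: int = 0,
) -> PopulationModel:
    """Draw a PopulationModel with Dirichlet frequencies and private alleles.

    Each population's support at a locus is `n_alleles` sizes from the
    locus ladder; `private_allele_plan` maps a population to loci where it
    receives one additional allele reserved for it alone (absent from every
    other population's support). Frequencies are Dirichlet(`concentration`)
    over the support, renormalized after private-allele injection.
    """
    if not populations:
        raise ValueError("need at least one population")
    if n_alleles < 1:
        raise ValueError("need at least one allele per locus")
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValueError("population names must be unique")
    plan = private_allele_plan or {}
    for pop in plan:
        if pop not in names:
            raise ValueError(f"private-allele plan names unknown population {pop!r}")

    rng = np.random.default_rng(seed)
    freqs: dict[str, dict[str, dict[int, float]]] = {p.name: {} for p in populations}

    for locus in panel.autosomal:
        ladder = locus.ladder()
        claimants = [p for p in names if locus.name in plan.get(p, [])]
        n_needed = n_alleles + len(claimants)
        if n_needed > len(ladder):
            raise ValueError(
                f"{locus.name}: ladder of {len(ladder)} sizes cannot host "
                f"{n_alleles} shared + {len(claimants)} private alleles"
            )
        chosen = rng.choice(len(ladder), size=n_needed, replace=False)
        shared = [ladder[i] for i in chosen[: n_alleles]]
        reserved = {p: ladder[i] for p, i in zip(claimants, chosen[n_alleles:])}
        for pop in names:
            support = sorted(shared + ([reserved[pop]] if pop in reserved else []))
            w = rng.dirichlet(np.full(len(support), concentration))
            w = w / w.sum()
            freqs[pop][locus.name] = dict(zip(support, w.tolist()))

    model = PopulationModel(
        panel=panel,
        populations=list(populations),
        allele_freqs=freqs,
        inbreeding_f=dict(inbreeding_f or {}),
    )
    model.validate()
    return model


def simulate_individuals(
    model: PopulationModel,
    n_per_population: dict[str, int] | int,
    sex_ratio: float = 0.5,
    sex_model: SexMarkerModel = KIWI_SEX_MODEL,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample true genotypes under HWE with inbreeding.

    Autosomal genotypes follow P(AA) = p^2 + f p(1-p) and
    P(AB) = 2pq(1-f), applied per locus independently: with probability f
    the individual is autozygous at the locus (one allele drawn, doubled),
    otherwise two alleles are drawn independently. Sex is female with
    probability `sex_ratio`; at the sex-linked locus females carry the W
    fragment plus one Z draw from the species (and lineage, where
    restricted) pool, males two Z draws.

    Returns a long table: sample, population, species, lineage, sex,
    locus, allele_a, allele_b (allele_a <= allele_b).
    """
    model.validate()
    rng = np.random.default_rng(seed)
    sex_locus = model.panel.sex_locus.name
    rows = []
    counter = 0
    for pop in model.populations:
        n = n_per_population if isinstance(n_per_population, int) else n_per_population[pop.name]
        f = model.inbreeding_f.get(pop.name, 0.0)
        z_pool = sex_model.z_pool(pop.species, pop.lineage)  # KeyError if unknown
        if not z_pool:
            raise ValueError(f"empty Z pool for {pop.species}/{pop.lineage}")
        for _ in range(n):
            counter += 1
            sample = f"{pop.name}_{counter:04d}"
            sex = "F" if rng.random() < sex_ratio else "M"
            for locus in model.panel.loci:
                if locus.sex_linked:
                    z = int(z_pool[rng.integers(len(z_pool))])
                    if sex == "F":
                        a, b = sorted((sex_model.w_size, z))
                    else:
                        z2 = int(z_pool[rng.integers(len(z_pool))])
                        a, b = sorted((z, z2))
                else:
                    fr = model.allele_freqs[pop.name][locus.name]
                    sizes = np.array(sorted(fr))
                    p = np.array([fr[s] for s in sizes])
                    if rng.random() < f:
                        a = b = int(rng.choice(sizes, p=p))
                    else:
                        a, b = sorted(int(x) for x in rng.choice(sizes, size=2, p=p))
                rows.append(
                    (sample, pop.name, pop.species, pop.lineage, sex, locus.name, a, b)
                )
    truth = pd.DataFrame(
        rows,
        columns=["sample", "population", "species", "lineage", "sex", "locus",
                 "allele_a", "allele_b"],
    )
    return truth


def simulate_replicates(
    truth: pd.DataFrame,
    error_model: ErrorModel,
    panel: PanelDefinition,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate each true genotype through the PCR error process.

    Per replicate: with `fail_prob` the amplification fails (empty
    observation); otherwise the true allele set is observed, minus one
    uniformly chosen allele with `ado_prob` when heterozygous, plus a
    stutter artifact (one repeat unit off a true allele, never equal to a
    true allele, clipped inside the locus size range) with `fa_prob`.
    Generation order is fixed (truth row order x replicate index), so a
    fixed seed gives byte-identical tables.
    """
    rng = np.random.default_rng(seed)
    em = error_model
    rows = []
    for rec in truth.itertuples():
        locus = panel[rec.locus]
        true_alleles = (int(rec.allele_a), int(rec.allele_b))
        for rep in range(1, em.replicates + 1):
            if rng.random() < em.fail_prob:
                obs: tuple[int, ...] = ()
            else:
                alleles = set(true_alleles)
                if len(alleles) == 2 and rng.random() < em.ado_prob:
                    alleles.discard(
                        true_alleles[rng.integers(2)]
                    )
                if rng.random() < em.fa_prob:
                    fa = _stutter_allele(true_alleles, locus, rng)
                    if fa is not None:
                        alleles.add(fa)
                obs = tuple(sorted(alleles))
            rows.append(
                (rec.sample, rec.population, rec.species, rec.locus, rep, obs)
            )
    return pd.DataFrame(
        rows, columns=["sample", "population", "species", "locus", "replicate", "alleles"]
    )


def _stutter_allele(true_alleles, locus, rng) -> int | None:
    lo, hi = locus.size_range
    candidates = sorted(
        {a + d * locus.repeat_unit for a in set(true_alleles) for d in (-1, 1)}
        - set(true_alleles)
    )
    candidates = [c for c in candidates if lo <= c <= hi]
    if not candidates:
        return None
    return int(candidates[rng.integers(len(candidates))])


def default_standard_concentrations(
    top: float = 5.0, bottom: float = 0.002, n: int = 10
) -> np.ndarray:
    """Geometric dilution series for the quantification standards
    (ten dilutions from 5 down to 0.002 ng/ul by default)."""
    return np.geomspace(top, bottom, n)


def simulate_qpcr(
    concentrations: dict[str, float],
    slope: float = -3.3219,
    intercept: float = 21.0,
    noise_sd: float = 0.0,
    inhibition_shifts: dict[str, float] | None = None,
    seed: int = 0,
    standards: np.ndarray | None = None,
    n_standard_reps: int = 3,
    n_unknown_reps: int = 3,
    n_spiked_reps: int = 2,
    n_control_reps: int = 3,
    spike_concentration: float = 2.5,
) -> pd.DataFrame:
    """Simulate a qPCR plate: quantification standards, unknowns, and an
    inhibition block of spiked samples against spike-only positive controls.

    Cq = intercept + slope * log10(concentration) + noise (+ shift for a
    sample's spiked wells). Standards default to ten serial dilutions from
    5 to 0.002 ng/ul run in triplicate; spiked wells carry the spike
    concentration so that, absent inhibitors, their Cq matches the positive
    control and the downstream dCq statistic recovers the injected shift.
    """
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    for s, c in concentrations.items():
        if c <= 0:
            raise ValueError(f"non-positive concentration for sample {s!r}")
    rng = np.random.default_rng(seed)
    shifts = inhibition_shifts or {}
    if standards is None:
        standards = default_standard_concentrations()

    def cq_of(conc: float, shift: float = 0.0) -> float:
        return intercept + slope * math.log10(conc) + shift + rng.normal(0, noise_sd)

    rows = []
    w = 0
    for conc in standards:
        for _ in range(n_standard_reps):
            w += 1
            rows.append((f"W{w:03d}", "", "standard", conc, cq_of(conc)))
    for sample in sorted(concentrations):
        for _ in range(n_unknown_reps):
            w += 1
            rows.append((f"W{w:03d}", sample, "unknown", np.nan,
                         cq_of(concentrations[sample])))
    for sample in sorted(concentrations):
        for _ in range(n_spiked_reps):
            w += 1
            rows.append((f"W{w:03d}", sample, "spiked_sample", np.nan,
                         cq_of(spike_concentration, shifts.get(sample, 0.0))))
    for _ in range(n_control_reps):
        w += 1
        rows.append((f"W{w:03d}", "", "positive_control", np.nan,
                     cq_of(spike_concentration)))
    return pd.DataFrame(rows, columns=["well", "sample", "role", "concentration", "cq"])
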