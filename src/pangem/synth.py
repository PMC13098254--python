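"""Synthetic multi-strain worlds with full ground truth.

The generator emulates the study design downstream stages expect: a strain
panel with core / accessory / rare gene families and per-strain allele
variation; a toy universal metabolic network of linear catabolic pathways,
each reaction gated by one gene family, so that a strain's family content
determines its true growth phenotype; and phenotype-microarray plates with
sigmoidal respiration traces for true growers and flat noisy baselines for
non-growers and negative controls.

All randomness flows from one root seed through named child streams
(genomes, alleles, network, plates) so adding a stage never perturbs
another stage's draws, and a fixed seed reproduces the world byte for byte.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .network import Medium, MetabolicNetwork, Metabolite, Reaction, save_json
from .fba import GROWTH_TOLERANCE, fba
from .phenotype import PlateReadings

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_STREAMS = {"genomes": 0, "alleles": 1, "network": 2, "plates": 3, "dropout": 4}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, named child stream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class WorldConfig:
    n_strains: int = 24
    n_core_families: int = 30
    n_accessory_families: int = 45
    n_rare_families: int = 10
    accessory_presence_prob: float = 0.7
    allele_mutation_rate: float = 0.02  # substitutions per site per strain
    indel_rate: float = 0.0  # optional stress switch; substitution-only by default
    protein_length_range: tuple[int, int] = (120, 250)
    n_substrates: int = 8
    n_pathways: int = 8
    pathway_length_range: tuple[int, int] = (2, 4)
    grower_signal_amplitude: float = 200.0
    baseline_signal: float = 10.0
    noise_sd: float = 5.0
    n_timepoints: int = 97  # one reading each 30 min over a 48 h run
    total_time_h: float = 48.0
    n_control_wells: int = 3
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_strains", "n_core_families", "n_substrates", "n_timepoints", "n_control_wells", "n_replicates", "n_pathways"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_accessory_families", "n_rare_families"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.accessory_presence_prob <= 1.0:
            raise ConfigError("accessory_presence_prob must be in [0, 1]")
        for name in ("allele_mutation_rate", "indel_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        lo, hi = self.protein_length_range
        if not (1 <= lo <= hi):
            raise ConfigError("protein_length_range must satisfy 1 <= min <= max")
        plo, phi = self.pathway_length_range
        if not (1 <= plo <= phi):
            raise ConfigError("pathway_length_range must satisfy 1 <= min <= max")
        if self.n_pathways > self.n_substrates:
            raise ConfigError("n_pathways cannot exceed n_substrates (one substrate per pathway)")
        if phi > self.n_core_families:
            raise ConfigError("pathway_length_range max exceeds the core families available to gate the core pathway")
        if (self.n_pathways - 1) * phi > self.n_accessory_families:
            raise ConfigError(
                f"{self.n_pathways - 1} accessory pathways of up to {phi} reactions need "
                f"{(self.n_pathways - 1) * phi} distinct accessory families; only "
                f"{self.n_accessory_families} available"
            )


@dataclass
class SyntheticWorld:
    config: WorldConfig
    strains: list[str]
    families: list[str]
    reference_sequences: dict[str, str]  # family -> reference protein
    proteomes: dict[str, list[tuple[str, str]]]  # strain -> [(gene id, sequence)]
    true_family_of_gene: dict[str, str]
    universal_network: MetabolicNetwork
    substrates: list[str]
    pathway_families: dict[str, list[str]]  # substrate -> gating families in pathway order
    true_gene_content: dict[str, set[str]]
    truth_presence: pd.DataFrame  # strains x families, 0/1
    true_phenotype: pd.DataFrame  # strains x substrates, bool
    plate_readings: dict[str, list[PlateReadings]] = field(default_factory=dict)
    medium: Medium = field(default_factory=Medium)

    def family_content(self, strain: str) -> set[str]:
        row = self.truth_presence.loc[strain]
        return set(row.index[row == 1])

    def strain_true_network(self, strain: str) -> MetabolicNetwork:
        net, _ = self.universal_network.restrict_to_genes(self.family_content(strain), f"{strain}_true")
        return net

    def pan_proteins(self) -> dict[str, str]:
        """Reference protein per family: the pan-genome side of BBH mapping."""
        return dict(self.reference_sequences)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _mutate(seq: str, rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < rate
    if mask.any():
        idx = np.flatnonzero(mask)
        for i in idx:
            choices = AMINO_ACIDS[AMINO_ACIDS != arr[i]]
            arr[i] = rng.choice(choices)
    out = "".join(arr)
    if indel_rate > 0:
        dele = rng.random(len(out)) < indel_rate
        out = "".join(ch for ch, d in zip(out, dele) if not d)
        if not out:
            out = seq[0]
    return out


def _build_universal_network(config: WorldConfig, substrates, core_ids, accessory_ids, rng) -> tuple[MetabolicNetwork, dict[str, list[str]]]:
    mets = [Metabolite("bm_c", "c", "biomass precursor")]
    rxns = [Reaction("BIOMASS", {"bm_c": -1.0}, 0.0, 1000.0, subsystem="biomass", name="biomass sink")]
    pathway_families: dict[str, list[str]] = {}
    acc_cursor = 0
    for i in range(config.n_pathways):
        sub = substrates[i]
        length = int(rng.integers(config.pathway_length_range[0], config.pathway_length_range[1] + 1))
        if i == 0:  # universally carried pathway (glucose-like), gated by core families
            gates = list(core_ids[:length])
        else:
            gates = list(accessory_ids[acc_cursor : acc_cursor + length])
            acc_cursor += length
        pathway_families[sub] = gates
        m_e = Metabolite(f"{sub}_e", "e")
        m_c = Metabolite(f"{sub}_c", "c")
        mets += [m_e, m_c]
        rxns.append(Reaction(f"EX_{sub}_e", {m_e.id: -1.0}, 0.0, 1000.0, subsystem="exchange"))
        # gates[0] gates the uptake transporter; gates[1:] gate the interior
        # chain from sub_c to the biomass precursor at unit yield throughout
        rxns.append(
            Reaction(f"T_{sub}", {m_e.id: -1.0, m_c.id: 1.0}, 0.0, 1000.0, gene_reaction_rule=gates[0], subsystem=f"{sub} transport")
        )
        chain = [m_c.id]
        for j in range(1, length - 1):
            mid = f"{sub}_i{j}_c"
            mets.append(Metabolite(mid, "c"))
            chain.append(mid)
        chain.append("bm_c")
        if length == 1:
            rxns.append(Reaction(f"P_{sub}_1", {m_c.id: -1.0, "bm_c": 1.0}, 0.0, 1000.0, gene_reaction_rule=gates[0], subsystem=f"{sub} catabolism"))
        else:
            for j in range(1, length):
                rxns.append(
                    Reaction(f"P_{sub}_{j}", {chain[j - 1]: -1.0, chain[j]: 1.0}, 0.0, 1000.0, gene_reaction_rule=gates[j], subsystem=f"{sub} catabolism")
                )
    net = MetabolicNetwork("universal_toy", mets, rxns, objective="BIOMASS")
    return net, pathway_families


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate strains, alleles, the toy network, truth tables, and plates.

    Core families are present in every strain, accessory families in each
    strain independently with ``accessory_presence_prob``, rare families in
    exactly one randomly chosen strain.  Each strain's copy of a family is
    the family reference mutated at ``allele_mutation_rate`` per site
    (substitutions only by default).  True phenotypes are read off the
    gene-gated pathways and re-verified by FBA on every strain-restricted
    network before the world is returned.
    """
    config.validate()
    rng_gen = stream_rng(config.seed, "genomes")
    rng_all = stream_rng(config.seed, "alleles")
    rng_net = stream_rng(config.seed, "network")

    strains = [f"S{i+1:03d}" for i in range(config.n_strains)]
    core_ids = [f"C{i+1:04d}" for i in range(config.n_core_families)]
    acc_ids = [f"A{i+1:04d}" for i in range(config.n_accessory_families)]
    rare_ids = [f"R{i+1:04d}" for i in range(config.n_rare_families)]
    families = core_ids + acc_ids + rare_ids

    lo, hi = config.protein_length_range
    reference = {}
    for fam in families:
        length = int(rng_gen.integers(lo, hi + 1))
        reference[fam] = "".join(rng_gen.choice(AMINO_ACIDS, size=length))

    presence = pd.DataFrame(0, index=pd.Index(strains, name="strain"), columns=pd.Index(families, name="family"), dtype=int)
    presence.loc[:, core_ids] = 1
    for fam in acc_ids:
        presence[fam] = (rng_gen.random(config.n_strains) < config.accessory_presence_prob).astype(int)
    for fam in rare_ids:
        presence.loc[strains[rng_gen.integers(config.n_strains)], fam] = 1

    proteomes: dict[str, list[tuple[str, str]]] = {}
    true_family_of_gene: dict[str, str] = {}
    true_gene_content: dict[str, set[str]] = {}
    for strain in strains:
        genes = []
        for fam in families:
            if presence.loc[strain, fam]:
                gid = f"{strain}_{fam}"
                seq = _mutate(reference[fam], config.allele_mutation_rate, config.indel_rate, rng_all)
                genes.append((gid, seq))
                true_family_of_gene[gid] = fam
        proteomes[strain] = genes
        true_gene_content[strain] = {g for g, _ in genes}

    substrates = [f"sub{i+1:02d}" for i in range(config.n_substrates)]
    network, pathway_families = _build_universal_network(config, substrates, core_ids, acc_ids, rng_net)

    phen = pd.DataFrame(False, index=pd.Index(strains, name="strain"), columns=pd.Index(substrates, name="substrate"))
    for strain in strains:
        fams = set(presence.columns[presence.loc[strain] == 1])
        for sub in substrates:
            gates = pathway_families.get(sub)
            phen.loc[strain, sub] = gates is not None and set(gates) <= fams

    world = SyntheticWorld(
        config=config,
        strains=strains,
        families=families,
        reference_sequences=reference,
        proteomes=proteomes,
        true_family_of_gene=true_family_of_gene,
        universal_network=network,
        substrates=substrates,
        pathway_families=pathway_families,
        true_gene_content=true_gene_content,
        truth_presence=presence,
        true_phenotype=phen,
    )
    _assert_self_consistent(world)
    world.plate_readings = generate_plate_traces(world, config)
    return world


def _assert_self_consistent(world: SyntheticWorld) -> None:
    """FBA on every strain-restricted network must reproduce true_phenotype."""
    for strain in world.strains:
        net = world.strain_true_network(strain)
        for sub in world.substrates:
            ex = f"EX_{sub}_e"
            if ex not in net.reactions:
                grows = False
            else:
                grows = fba(net, world.medium, ex, uptake=10.0).grows(GROWTH_TOLERANCE)
            expected = bool(world.true_phenotype.loc[strain, sub])
            if grows != expected:
                raise AssertionError(
                    f"self-consistency failure: FBA says grows={grows} but truth says {expected} "
                    f"for ({strain}, {sub})"
                )


# ---------------------------------------------------------------------------
# Plate simulation
# ---------------------------------------------------------------------------


def simulate_plates(
    truth: pd.DataFrame,
    config: WorldConfig,
    rng: np.random.Generator,
) -> dict[str, list[PlateReadings]]:
    """Simulate replicate plates for an arbitrary strain x substrate truth table.

    Grower wells follow a logistic curve rising from the baseline to
    ``grower_signal_amplitude``; non-grower and control wells stay at the
    baseline; all wells receive i.i.d. Gaussian noise of sd ``noise_sd``.
    """
    t = np.linspace(0.0, config.total_time_h, config.n_timepoints)
    t0 = 0.5 * config.total_time_h
    rate = 12.0 / config.total_time_h  # 10-90% rise over ~37% of the run
    raw = 1.0 / (1.0 + np.exp(-rate * (t - t0)))
    # rescale to [0, 1] over the run so a noiseless grower starts exactly at
    # the baseline and its maximum is exactly the amplitude
    logistic = (raw - raw[0]) / (raw[-1] - raw[0])
    base, amp = config.baseline_signal, config.grower_signal_amplitude

    out: dict[str, list[PlateReadings]] = {}
    substrates = list(truth.columns)
    n_sub, n_ctl = len(substrates), config.n_control_wells
    wells = pd.DataFrame(
        {
            "well": [f"W{i+1:03d}" for i in range(n_sub + n_ctl)],
            "substrate": substrates + [""] * n_ctl,
            "is_control": [False] * n_sub + [True] * n_ctl,
        }
    )
    for strain in truth.index:
        grows = truth.loc[strain].to_numpy(dtype=bool)
        clean = np.empty((n_sub + n_ctl, t.size))
        clean[:n_sub] = np.where(grows[:, None], base + (amp - base) * logistic[None, :], base)
        clean[n_sub:] = base
        plates = []
        for rep in range(config.n_replicates):
            noise = rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd > 0 else 0.0
            plates.append(
                PlateReadings(
                    strain=str(strain),
                    replicate=f"r{rep+1}",
                    times=t,
                    signals=clean + noise,
                    wells=wells.copy(),
                )
            )
        out[str(strain)] = plates
    return out


def generate_plate_traces(world: SyntheticWorld, config: WorldConfig | None = None) -> dict[str, list[PlateReadings]]:
    """Plates for a generated world: one trace per (strain, substrate) plus controls."""
    config = config or world.config
    rng = stream_rng(config.seed, "plates")
    return simulate_plates(world.true_phenotype, config, rng)


# ---------------------------------------------------------------------------
# Persistence (plain-text formats only)
# ---------------------------------------------------------------------------


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Persist a world: per-strain FASTA, plates CSV, truth CSVs, model JSON."""
    outdir = Path(outdir)
    prot_dir = outdir / "proteomes"
    prot_dir.mkdir(parents=True, exist_ok=True)
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    for strain, genes in world.proteomes.items():
        records = [SeqRecord(Seq(seq), id=f"{strain}|{gid}", description="") for gid, seq in genes]
        seqio_write(records, prot_dir / f"{strain}.faa", "fasta")
    pan_records = [
        SeqRecord(Seq(seq), id=f"pan|{fam}", description="") for fam, seq in world.reference_sequences.items()
    ]
    seqio_write(pan_records, outdir / "pan_proteins.faa", "fasta")

    rows = []
    for strain, plates in world.plate_readings.items():
        for plate in plates:
            for i, wrow in plate.wells.iterrows():
                for tt, sig in zip(plate.times, plate.signals[i]):
                    rows.append(
                        (strain, plate.replicate, wrow["well"], wrow["substrate"], bool(wrow["is_control"]), tt, sig)
                    )
    pd.DataFrame(
        rows, columns=["strain", "replicate", "well", "substrate", "is_control", "time_h", "signal"]
    ).to_csv(outdir / "plates.csv", index=False, float_format="%.17g")

    world.truth_presence.to_csv(outdir / "truth_presence.csv")
    world.true_phenotype.astype(int).to_csv(outdir / "true_phenotype.csv")
    save_json(world.universal_network, outdir / "universal_model.json")
    (outdir / "pathway_families.json").write_text(json.dumps(world.pathway_families, indent=1, sort_keys=True) + "\n")


def load_plates_csv(path: str | Path) -> list[PlateReadings]:
    """Read the long-format plates CSV back into per-(strain, replicate) plates."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    plates = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        pivot = grp.pivot_table(index="well", columns="time_h", values="signal", sort=True)
        meta = grp.drop_duplicates("well").set_index("well").loc[pivot.index]
        wells = pd.DataFrame(
            {
                "well": pivot.index,
                "substrate": meta["substrate"].astype(str).to_numpy(),
                "is_control": meta["is_control"].astype(bool).to_numpy(),
            }
        ).reset_index(drop=True)
        plates.append(
            PlateReadings(
                strain=str(strain),
                replicate=str(rep),
                times=pivot.columns.to_numpy(dtype=float),
                signals=pivot.to_numpy(dtype=float),
                wells=wells,
            )
        )
    return plates
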