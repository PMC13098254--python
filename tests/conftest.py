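import numpy as np
import pandas as pd
import pytest

from pangem.network import MetabolicNetwork, Metabolite, Reaction
from pangem.phenotype import PlateReadings
from pangem.synth import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """Six-strain world, small enough for exhaustive truth comparisons."""
    return generate_world(
        WorldConfig(
            n_strains=6,
            n_core_families=8,
            n_accessory_families=12,
            n_rare_families=2,
            n_substrates=4,
            n_pathways=4,
            pathway_length_range=(1, 3),
            protein_length_range=(100, 160),
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions with a fixed seed."""
    return generate_world(WorldConfig(seed=11))


def chain_network(n_steps: int = 3, yield_coef: float = 1.0, gene: str | None = None) -> MetabolicNetwork:
    """Linear toy: EX_s_e -> transport -> n_steps conversions -> biomass sink."""
    mets = [Metabolite("s_e", "e"), Metabolite("s_c", "c"), Metabolite("bm_c", "c")]
    nodes = ["s_c"]
    for j in range(1, n_steps):
        mets.append(Metabolite(f"i{j}_c", "c"))
        nodes.append(f"i{j}_c")
    nodes.append("bm_c")
    rxns = [
        Reaction("EX_s_e", {"s_e": -1.0}),
        Reaction("T_s", {"s_e": -1.0, "s_c": 1.0}, gene_reaction_rule=gene or ""),
    ]
    for j in range(n_steps):
        coef = yield_coef if nodes[j + 1] == "bm_c" else 1.0
        rxns.append(Reaction(f"R{j+1}", {nodes[j]: -1.0, nodes[j + 1]: coef}))
    rxns.append(Reaction("BIOMASS", {"bm_c": -1.0}))
    return MetabolicNetwork("chain", mets, rxns, "BIOMASS")


def constant_plate(strain, sub_values: dict[str, float], control_values: list[float], n_timepoints: int = 97):
    """Plate of constant traces: smoothed max equals the constant itself."""
    t = np.linspace(0.0, 48.0, n_timepoints)
    names = list(sub_values)
    signals = np.array([[v] * n_timepoints for v in list(sub_values.values()) + control_values], dtype=float)
    wells = pd.DataFrame(
        {
            "well": [f"W{i:03d}" for i in range(len(names) + len(control_values))],
            "substrate": names + [""] * len(control_values),
            "is_control": [False] * len(names) + [True] * len(control_values),
        }
    )
    return PlateReadings(strain=strain, replicate="r1", times=t, signals=signals, wells=wells)
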