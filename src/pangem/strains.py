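"""Strain-specific model derivation, growth prediction, and reaction-content
analysis across a strain panel.

A strain model is the pan-model pruned by orthology: pan genes without a
reciprocal best hit in the strain's proteome are removed, each reaction's
GPR is re-evaluated over the survivors, reactions whose rule turns false
are dropped (empty-rule reactions stay), and orphan metabolites are pruned.
Growth phenotypes are predicted by FBA with each substrate as sole carbon
source; reaction content across models is classified core/accessory/rare
by frequency and embedded by multiple correspondence analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelError
from .fba import GROWTH_TOLERANCE, fba
from .network import Medium, MetabolicNetwork
from .phenotype import GrowthCallMatrix

CORE_FREQUENCY = 0.98  # core: present in >= 98% of strain models
RARE_FREQUENCY = 0.10  # rare: present in < 10%


@dataclass
class StrainModel:
    strain: str
    network: MetabolicNetwork
    removed_genes: list[str] = field(default_factory=list)
    removed_reactions: list[str] = field(default_factory=list)
    gapfilled_reactions: list[str] = field(default_factory=list)


def derive_strain_model(pan: MetabolicNetwork, bbh: pd.DataFrame, strain: str = "strain") -> StrainModel:
    """Prune the pan-model to the genes with a BBH ortholog in the strain."""
    surviving = set(bbh["pan_gene"]) & set(pan.genes)
    removed_genes = sorted(set(pan.genes) - surviving)
    net, removed_rxns = pan.restrict_to_genes(surviving, f"{strain}_model")
    return StrainModel(strain, net, removed_genes, removed_rxns)


def predict_growth_matrix(
    models: list[StrainModel],
    substrates: list[str],
    medium: Medium | None = None,
    uptake: float = 10.0,
    growth_tolerance: float = GROWTH_TOLERANCE,
) -> GrowthCallMatrix:
    """FBA growth/no-growth per (strain, substrate exchange) at sole-carbon uptake.

    A substrate whose exchange reaction is absent from a strain model is
    predicted no-growth: missing transport is a statement of the model, not
    an error.
    """
    strains = [m.strain for m in models]
    calls = pd.DataFrame(
        False, index=pd.Index(strains, name="strain"), columns=pd.Index(list(substrates), name="substrate")
    )
    for m in models:
        for ex in substrates:
            if ex not in m.network.reactions:
                continue
            sol = fba(m.network, medium, ex, uptake)
            calls.loc[m.strain, ex] = sol.grows(growth_tolerance)
    return GrowthCallMatrix.from_bool(calls)


@dataclass
class PredictionScore:
    accuracy: float
    false_positive_rate: float
    false_negative_rate: float
    n_overlap: int
    per_substrate: pd.DataFrame  # substrate, fp, fn, n

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
            "n_overlap": self.n_overlap,
        }


def score_predictions(pred: GrowthCallMatrix, obs: GrowthCallMatrix) -> PredictionScore:
    """Cell-wise accuracy with FP/FN rates over the overlapping cells."""
    strains = sorted(set(pred.strains) & set(obs.strains))
    subs = sorted(set(pred.substrates) & set(obs.substrates))
    if not strains or not subs:
        raise ValueError("no overlapping (strain, substrate) cells to score")
    p = pred.calls.loc[strains, subs].to_numpy()
    o = obs.calls.loc[strains, subs].to_numpy()
    n = p.size
    fp = p & ~o
    fn = ~p & o
    per_sub = pd.DataFrame(
        {
            "substrate": subs,
            "fp": fp.sum(axis=0),
            "fn": fn.sum(axis=0),
            "n": [len(strains)] * len(subs),
        }
    )
    return PredictionScore(
        accuracy=float((p == o).mean()),
        false_positive_rate=float(fp.sum() / n),
        false_negative_rate=float(fn.sum() / n),
        n_overlap=n,
        per_substrate=per_sub,
    )


@dataclass
class ReactionClassification:
    frequency: pd.Series  # reaction id -> fraction of strain models containing it
    classes: pd.Series  # reaction id -> {"core", "accessory", "rare"}

    def counts(self) -> dict[str, int]:
        c = self.classes.value_counts()
        return {k: int(c.get(k, 0)) for k in ("core", "accessory", "rare")}


def classify_reactions(
    models: list[StrainModel],
    core_frequency: float = CORE_FREQUENCY,
    rare_frequency: float = RARE_FREQUENCY,
) -> ReactionClassification:
    """Classify the union reaction set by cross-strain frequency.

    core iff frequency >= ``core_frequency``; rare iff frequency <
    ``rare_frequency``; accessory otherwise.  The three classes partition
    the reactions.
    """
    if not models:
        raise ValueError("need at least one strain model")
    all_rxns = sorted({r for m in models for r in m.network.reactions})
    counts = pd.Series(0, index=pd.Index(all_rxns, name="reaction"), dtype=int)
    for m in models:
        counts[list(m.network.reactions)] += 1
    freq = counts / len(models)
    classes = pd.Series(
        np.where(freq >= core_frequency, "core", np.where(freq < rare_frequency, "rare", "accessory")),
        index=freq.index,
    )
    return ReactionClassification(freq, classes)


@dataclass
class McaResult:
    coordinates: pd.DataFrame  # strains x axes, row principal coordinates
    inertia: np.ndarray  # per-axis fraction of total inertia, non-increasing


def reaction_presence_frame(models: list[StrainModel]) -> pd.DataFrame:
    all_rxns = sorted({r for m in models for r in m.network.reactions})
    return pd.DataFrame(
        [[int(r in m.network.reactions) for r in all_rxns] for m in models],
        index=pd.Index([m.strain for m in models], name="strain"),
        columns=pd.Index(all_rxns, name="reaction"),
    )


def correspondence_analysis(indicator: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row principal coordinates and inertia fractions of an indicator matrix.

    Standard CA via SVD of the standardised residual matrix
    ``D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` with P the correspondence matrix.
    All-zero columns (unobserved categories) are dropped beforehand.
    """
    Z = indicator[:, indicator.sum(axis=0) > 0].astype(float)
    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    # trailing ~zero singular values carry no inertia; the trivial dimension
    # is already removed by centring
    total = (sv**2).sum()
    if total <= 1e-12:
        raise ModelError("constant reaction-content matrix: zero inertia, MCA undefined")
    coords = (U * sv) / np.sqrt(r)[:, None]
    inertia = sv**2 / total
    kk = min(k, sv.size)
    return coords[:, :kk], inertia[:kk]


def mca_strains(models: list[StrainModel], k: int = 2) -> McaResult:
    """Multiple correspondence analysis of reaction presence/absence.

    Uses the indicator-matrix formulation with two categories (present,
    absent) per reaction; returns per-strain principal coordinates on the
    first ``k`` axes and the principal-inertia fractions.
    """
    if len(models) < 3:
        raise ValueError("MCA needs >= 3 strain models")
    presence = reaction_presence_frame(models)
    X = presence.to_numpy()
    indicator = np.concatenate([X, 1 - X], axis=1)
    coords, inertia = correspondence_analysis(indicator, k)
    frame = pd.DataFrame(
        coords, index=presence.index, columns=[f"axis_{i+1}" for i in range(coords.shape[1])]
    )
    return McaResult(frame, inertia)
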