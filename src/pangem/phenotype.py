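"""Growth calling from kinetic respiration traces and activity summaries.

A Biolog-style phenotype microarray records one dye-reduction kinetic trace
per well.  The calling procedure: Savitzky-Golay smoothing of each trace,
extraction of the maximum smoothed signal, a one-sided z-test of each
substrate well against the pooled negative-control wells, Bonferroni
correction over the substrate wells of the plate, and a growth call when the
adjusted P-value falls below alpha (strictly).  Replicate plates are
combined conservatively: a (strain, substrate) cell is called growth only if
it is significant in every replicate (a majority rule is available).

The module also carries the compound-group bookkeeping of the PM01/PM02A
panel used for the metabolic activity index.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import norm

from .errors import DegenerateControlsError, TraceError

logger = logging.getLogger(__name__)

#: Compound groups of the 190 PM01/PM02A sole-carbon substrates.
BIOLOG_GROUP_SIZES: dict[str, int] = {
    "organic acids": 41,
    "L-amino acids": 21,
    "monosaccharides": 17,
    "oligosaccharides": 24,
    "sugar acids and alcohols": 26,
    "modified sugars": 26,
    "aromatics": 7,
    "others": 28,
}
#: Aromatic substrates assayed separately on agar plates.
N_AGAR_AROMATICS = 15
#: PM substrates with a BiGG identifier usable for model validation.
N_BIOLOG_WITH_BIGG = 144


def substrate_bookkeeping() -> dict[str, int]:
    """Panel-level substrate counts derived from the compound groups."""
    n_biolog = sum(BIOLOG_GROUP_SIZES.values())
    return {
        "n_biolog_substrates": n_biolog,
        "n_total_substrates": n_biolog + N_AGAR_AROMATICS,
        "n_aromatics_total": BIOLOG_GROUP_SIZES["aromatics"] + N_AGAR_AROMATICS,
        "n_without_bigg": n_biolog - N_BIOLOG_WITH_BIGG,
    }


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class KineticTrace:
    well: str
    substrate: str | None  # None for a negative-control well
    times: np.ndarray  # hours, strictly increasing
    signals: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.size < 2:
            raise TraceError(f"trace {self.well}: needs >= 2 time points")
        if self.times.size != self.signals.size:
            raise TraceError(f"trace {self.well}: time/signal length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise TraceError(f"trace {self.well}: time points must be strictly increasing")
        if np.any(~np.isfinite(self.signals)):
            raise TraceError(f"trace {self.well}: missing or non-finite signal values")

    @property
    def is_control(self) -> bool:
        return self.substrate is None


@dataclass
class PlateReadings:
    """All traces of one replicate plate for one strain."""

    strain: str
    replicate: str
    times: np.ndarray  # (T,) shared time grid, hours
    signals: np.ndarray  # (W, T)
    wells: pd.DataFrame  # columns: well, substrate, is_control

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape != (len(self.wells), self.times.size):
            raise TraceError(f"plate {self.strain}/{self.replicate}: signal matrix shape mismatch")

    def traces(self) -> list[KineticTrace]:
        out = []
        for i, row in self.wells.reset_index(drop=True).iterrows():
            sub = None if row["is_control"] else row["substrate"]
            out.append(KineticTrace(row["well"], sub, self.times, self.signals[i]))
        return out


@dataclass
class CallConfig:
    sg_window: int = 50
    sg_degree: int = 3
    alpha: float = 0.05
    correction: str = "bonferroni"
    min_controls: int = 2
    replicate_rule: str = "all"  # "all" (conservative AND) or "majority"
    sigma_floor: bool = False  # replace sigma=0 by 1e-6 * |control mean|

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.correction != "bonferroni":
            raise ValueError(f"unsupported correction {self.correction!r}")
        if self.replicate_rule not in ("all", "majority"):
            raise ValueError(f"unsupported replicate rule {self.replicate_rule!r}")
        if self.sg_degree >= self.effective_window:
            raise ValueError("sg_degree must be smaller than the effective window length")

    @property
    def effective_window(self) -> int:
        """Savitzky-Golay needs an odd window; an even request is rounded up."""
        return self.sg_window if self.sg_window % 2 == 1 else self.sg_window + 1


@dataclass
class GrowthCallMatrix:
    """Binary strain x substrate calls with raw/adjusted p-values and max signals."""

    calls: pd.DataFrame  # bool
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    max_signal: pd.DataFrame

    @property
    def strains(self) -> list[str]:
        return list(self.calls.index)

    @property
    def substrates(self) -> list[str]:
        return list(self.calls.columns)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strains:
            for c in self.substrates:
                rows.append(
                    {
                        "strain": s,
                        "substrate": c,
                        "call": "growth" if self.calls.loc[s, c] else "no-growth",
                        "p_raw": self.p_raw.loc[s, c],
                        "p_adj": self.p_adj.loc[s, c],
                        "max_signal": self.max_signal.loc[s, c],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_bool(cls, calls: pd.DataFrame) -> "GrowthCallMatrix":
        """Wrap a plain truth table (e.g. agar-assay observations) without p-values."""
        nan = calls.astype(float) * np.nan
        return cls(calls.astype(bool), nan, nan.copy(), nan.copy())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _smooth_matrix(signals: np.ndarray, cfg: CallConfig, label: str = "trace") -> np.ndarray:
    window = cfg.effective_window
    if window != cfg.sg_window:
        logger.info("Savitzky-Golay window %d is even; using %d", cfg.sg_window, window)
    if signals.shape[-1] < window:
        raise TraceError(
            f"{label}: {signals.shape[-1]} time points is shorter than the smoothing window {window}"
        )
    return savgol_filter(signals, window_length=window, polyorder=cfg.sg_degree, axis=-1)


def smooth_trace(trace: KineticTrace, cfg: CallConfig | None = None) -> KineticTrace:
    """Savitzky-Golay smoothing on the trace's own time grid.

    A local least-squares polynomial fit; any signal that is itself a
    polynomial of degree <= ``sg_degree`` is reproduced exactly.
    """
    cfg = cfg or CallConfig()
    smoothed = _smooth_matrix(trace.signals[None, :], cfg, label=f"trace {trace.well}")[0]
    return replace(trace, signals=smoothed)


def max_signal(trace: KineticTrace) -> float:
    """Maximum signal over the full time course."""
    return float(np.max(trace.signals))


def _control_stats(maxima: np.ndarray, cfg: CallConfig, strain: str) -> tuple[float, float]:
    if maxima.size < cfg.min_controls:
        raise DegenerateControlsError(
            f"strain {strain}: {maxima.size} control wells pooled, need >= {cfg.min_controls}"
        )
    mu = float(np.mean(maxima))
    sigma = float(np.std(maxima, ddof=1))
    if sigma == 0.0:
        if not cfg.sigma_floor:
            raise DegenerateControlsError(
                f"strain {strain}: control wells have zero standard deviation"
            )
        sigma = 1e-6 * max(abs(mu), 1.0)
    return mu, sigma


def call_growth(readings: list[PlateReadings] | PlateReadings, cfg: CallConfig | None = None) -> GrowthCallMatrix:
    """Smooth, extract maxima, z-test against pooled controls, Bonferroni, call.

    Control maxima are pooled across a strain's replicate plates; each
    replicate's substrate wells are tested with multiplicity m = number of
    substrate wells on that replicate.  A cell is called growth when its
    adjusted P-value is strictly below alpha in every replicate
    (``replicate_rule="all"``) or in more than half of them (``"majority"``).
    The reported p-values and max signal per cell are the across-replicate
    worst-case (maximum) p and best-case (maximum) signal.
    """
    cfg = cfg or CallConfig()
    if isinstance(readings, PlateReadings):
        readings = [readings]
    by_strain: dict[str, list[PlateReadings]] = {}
    for plate in readings:
        by_strain.setdefault(plate.strain, []).append(plate)

    strains = sorted(by_strain)
    substrates: list[str] = sorted(
        {s for plates in by_strain.values() for p in plates for s in p.wells.loc[~p.wells["is_control"], "substrate"]}
    )
    shape = (len(strains), len(substrates))
    calls = np.zeros(shape, dtype=bool)
    p_raw = np.full(shape, np.nan)
    p_adj = np.full(shape, np.nan)
    mx = np.full(shape, np.nan)
    col = {c: j for j, c in enumerate(substrates)}

    for i, strain in enumerate(strains):
        plates = by_strain[strain]
        smoothed = [_smooth_matrix(p.signals, cfg, label=f"plate {strain}/{p.replicate}") for p in plates]
        maxima = [s.max(axis=1) for s in smoothed]
        ctrl = np.concatenate(
            [m[p.wells["is_control"].to_numpy()] for p, m in zip(plates, maxima)]
        )
        mu, sigma = _control_stats(ctrl, cfg, strain)
        sig_count = np.zeros(len(substrates), dtype=int)
        tested = np.zeros(len(substrates), dtype=int)
        for plate, m in zip(plates, maxima):
            mask = ~plate.wells["is_control"].to_numpy()
            subs = plate.wells.loc[mask, "substrate"].to_numpy()
            vals = m[mask]
            mult = int(mask.sum())
            z = (vals - mu) / sigma
            praw = norm.sf(z)
            padj = np.minimum(1.0, praw * mult)
            for c, v, pr, pa in zip(subs, vals, praw, padj):
                j = col[c]
                tested[j] += 1
                if pa < cfg.alpha:
                    sig_count[j] += 1
                p_raw[i, j] = pr if np.isnan(p_raw[i, j]) else max(p_raw[i, j], pr)
                p_adj[i, j] = pa if np.isnan(p_adj[i, j]) else max(p_adj[i, j], pa)
                mx[i, j] = v if np.isnan(mx[i, j]) else max(mx[i, j], v)
        if cfg.replicate_rule == "all":
            calls[i] = (tested > 0) & (sig_count == tested)
        else:
            calls[i] = (tested > 0) & (sig_count * 2 > tested)

    idx = pd.Index(strains, name="strain")
    cols = pd.Index(substrates, name="substrate")
    return GrowthCallMatrix(
        pd.DataFrame(calls, idx, cols),
        pd.DataFrame(p_raw, idx, cols),
        pd.DataFrame(p_adj, idx, cols),
        pd.DataFrame(mx, idx, cols),
    )


@dataclass
class CompoundGroup:
    name: str
    substrates: list[str]


@dataclass
class ActivityProfile:
    """Per-strain per-group activity fractions and the group-level index."""

    fractions: pd.DataFrame  # strains x groups, in [0, 1]
    index: pd.Series  # per group: mean fraction over strains ("metabolic activity index")


def group_activity(calls: GrowthCallMatrix, groups: list[CompoundGroup]) -> ActivityProfile:
    """Fraction of each group's substrates supporting activity, per strain.

    The metabolic activity index of a group is the arithmetic mean of that
    fraction over strains.  Groups must partition the call matrix's
    substrate universe.
    """
    seen: dict[str, str] = {}
    for g in groups:
        for s in g.substrates:
            if s in seen:
                raise ValueError(f"substrate {s!r} assigned to both {seen[s]!r} and {g.name!r}")
            seen[s] = g.name
    missing = sorted(set(calls.substrates) - set(seen))
    if missing:
        raise ValueError(f"substrates missing from all compound groups: {missing}")

    data = {}
    for g in groups:
        members = [s for s in g.substrates if s in calls.calls.columns]
        if not members:
            continue
        data[g.name] = calls.calls[members].mean(axis=1)
    fractions = pd.DataFrame(data)
    return ActivityProfile(fractions, fractions.mean(axis=0))


@dataclass
class AgreementResult:
    agreement: float
    n_overlap: int
    discordance: dict[str, int]  # a+/b- and a-/b+ counts


def assay_agreement(a: GrowthCallMatrix, b: GrowthCallMatrix) -> AgreementResult:
    """Fraction of overlapping (strain, substrate) cells with equal calls."""
    strains = sorted(set(a.strains) & set(b.strains))
    subs = sorted(set(a.substrates) & set(b.substrates))
    if not strains or not subs:
        raise ValueError("no overlapping (strain, substrate) cells between the two call matrices")
    ca = a.calls.loc[strains, subs].to_numpy()
    cb = b.calls.loc[strains, subs].to_numpy()
    n = ca.size
    agree = int((ca == cb).sum())
    return AgreementResult(
        agreement=agree / n,
        n_overlap=n,
        discordance={
            "a_pos_b_neg": int((ca & ~cb).sum()),
            "a_neg_b_pos": int((~ca & cb).sum()),
        },
    )
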