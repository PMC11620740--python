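"""Synthetic cohorts with the statistical structure of lineage-tracing data.

Three generative regimes back the validation of the variance estimator:

* **fixed-n cohorts** — every animal hosts exactly ``n`` precursors; each
  precursor independently recombines to one of the label channels (or
  stays unlabeled), so per-animal channel fractions are multinomially
  dispersed around the channel probabilities with variance ``p(1-p)/n``;
* **Poisson-seeded cohorts** — transplantation seeds a random number of
  precursors per recipient, ``n_i ~ Poisson(lambda)``; the extra
  between-animal variation inflates fraction variance and breaks the
  one-to-one estimator calibration at small ``lambda``;
* **two-color cultures** — wells seeded with a known number of cells
  from a two-color mix, with per-cell survival and neutral expansion;
  the in-vitro ground-truth sweep behind the log-linear validation.

Measurement noise is modeled as multinomial subsampling of a finite
number of recorded flow events from the animal's true composition
(``recorded_events=None`` disables it).  All generators are
deterministic under a fixed seed and emit tables in the cohort CSV
schema of :mod:`varicount.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "fixed_n_cohort",
    "poisson_seeded_cohort",
    "two_color_culture",
    "multispectral_cohort",
    "cohort_fractions",
]

_SCHEMA_CHANNELS = ("rfp", "yfp", "cfp", "gfp")
# recorded_events written to the schema when measurement noise is off;
# effectively infinite relative to any estimable precursor number
_NOISELESS_EVENTS = 10**12


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated cohort.

    Exactly one of ``n`` (fixed precursor count per animal) or ``lam``
    (Poisson mean seeding number) is set.  ``p_channels`` maps label
    channel names to recombination probabilities *within the labeled
    compartment* (must sum to 1); ``labeling_efficiency`` is the
    probability that a precursor carries any label at all.
    ``recorded_events=None`` means no measurement noise (fractions
    reported exactly).
    """

    n: int | None = None
    lam: float | None = None
    p_channels: Mapping[str, float] = field(
        default_factory=lambda: {"rfp": 0.5, "yfp": 0.5})
    labeling_efficiency: float = 1.0
    recorded_events: int | None = None
    n_animals: int = 20
    n_cohorts: int = 1
    seed: int | None = None

    def __post_init__(self):
        if (self.n is None) == (self.lam is None):
            raise ValueError("set exactly one of n (fixed) or lam (Poisson)")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be > 0")
        probs = list(self.p_channels.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("channel probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("channel probabilities must sum to 1")
        if not (0.0 < self.labeling_efficiency <= 1.0):
            raise ValueError("labeling_efficiency must be in (0, 1]")
        if self.recorded_events is not None and self.recorded_events < 1:
            raise ValueError("recorded_events must be >= 1 (or None)")
        if self.n_animals < 1 or self.n_cohorts < 1:
            raise ValueError("n_animals and n_cohorts must be >= 1")
        for ch in self.p_channels:
            if ch not in _SCHEMA_CHANNELS:
                raise ValueError(f"unknown channel {ch!r}; use {_SCHEMA_CHANNELS}")


def _measure(rng: np.random.Generator, comp: np.ndarray,
             recorded_events: int | None) -> np.ndarray:
    """Finite-event flow measurement: multinomial subsampling of the
    true per-animal composition ``comp`` (rows sum to 1)."""
    if recorded_events is None:
        return comp
    counts = rng.multinomial(recorded_events, comp)
    return counts / recorded_events


def _compose_rows(config: SimulationConfig, n_per_animal: np.ndarray,
                  rng: np.random.Generator, cohort: int,
                  flags: list[str] | None = None) -> pd.DataFrame:
    """Draw channel compositions for animals with given precursor counts
    and emit schema rows (percent scale)."""
    channels = list(config.p_channels)
    eff = config.labeling_efficiency
    # full per-precursor outcome: each labeled channel scaled by the
    # labeling efficiency, plus an explicit unlabeled slot
    pvals = np.array([eff * config.p_channels[c] for c in channels] + [1.0 - eff])
    m = n_per_animal.size
    comp = np.zeros((m, len(channels) + 1))
    pos = n_per_animal > 0
    if np.any(pos):
        counts = rng.multinomial(n_per_animal[pos], pvals)
        comp[pos] = counts / n_per_animal[pos, None]
    measured = comp.copy()
    if np.any(pos):
        measured[pos] = _measure(rng, comp[pos], config.recorded_events)

    events = (config.recorded_events if config.recorded_events is not None
              else _NOISELESS_EVENTS)
    rows = {
        "sample_id": [f"c{cohort}_a{i:03d}" for i in range(m)],
        "replicate": [f"rep{cohort}"] * m,
        "timepoint": ["t0"] * m,
        "cell_type": ["myeloid"] * m,
        "condition": ["sim"] * m,
        "recorded_events": [events] * m,
    }
    for ch in _SCHEMA_CHANNELS:
        if ch in channels:
            rows[f"{ch}_pct"] = measured[:, channels.index(ch)] * 100.0
        elif ch in ("rfp", "yfp", "cfp"):
            rows[f"{ch}_pct"] = np.zeros(m)
    if flags is not None:
        rows["flags"] = flags
    return pd.DataFrame(rows)


def fixed_n_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Cohorts in which every animal hosts exactly ``config.n`` precursors.

    Per animal: labeled channel counts are multinomial over ``n``
    precursors; the true channel fraction is count/n; the measured
    fraction adds finite-event counting noise when ``recorded_events``
    is finite.  Deterministic under a fixed seed.
    """
    if config.n is None:
        raise ValueError("fixed_n_cohort requires config.n")
    rng = np.random.default_rng(config.seed)
    frames = []
    for c in range(config.n_cohorts):
        n_arr = np.full(config.n_animals, config.n, dtype=np.int64)
        frames.append(_compose_rows(config, n_arr, rng, c))
    return pd.concat(frames, ignore_index=True)


def poisson_seeded_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Cohorts with per-animal precursor numbers ``n_i ~ Poisson(lam)``.

    Recipients seeded with zero precursors are emitted with the flag
    ``no-precursors`` (all-zero fractions) so downstream attrition is
    visible rather than silently dropped.
    """
    if config.lam is None:
        raise ValueError("poisson_seeded_cohort requires config.lam")
    rng = np.random.default_rng(config.seed)
    frames = []
    for c in range(config.n_cohorts):
        n_arr = rng.poisson(config.lam, config.n_animals).astype(np.int64)
        flags = ["no-precursors" if ni == 0 else "" for ni in n_arr]
        frames.append(_compose_rows(config, n_arr, rng, c, flags=flags))
    return pd.concat(frames, ignore_index=True)


def two_color_culture(
    seeded: int,
    survival_rate: float,
    mix_fraction: float,
    wells: int,
    recorded_events: int | None = None,
    seed: int | None = None,
    growth_generations: int = 0,
) -> pd.DataFrame:
    """Wells seeded with ``seeded`` cells from a two-color mix.

    Per well: survivors ~ Binomial(seeded, survival_rate); wells with no
    survivors are flagged ``no-survivors``.  Founders of the first color
    ~ Binomial(survivors, mix_fraction) and, under the default neutral
    expansion, the final fraction equals the founder fraction.  Setting
    ``growth_generations > 0`` switches on genetic-drift-style
    resampling: each generation the population doubles and the color
    count is redrawn binomially at the current fraction.  Finite
    ``recorded_events`` adds counting noise.

    Returns a table with columns ``well_id, seeded, survivors,
    bfp_fraction, flags``.
    """
    if seeded < 1:
        raise ValueError("seeded must be >= 1")
    for name, v in (("survival_rate", survival_rate), ("mix_fraction", mix_fraction)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must be in (0, 1]")
    if wells < 1:
        raise ValueError("wells must be >= 1")
    rng = np.random.default_rng(seed)
    survivors = rng.binomial(seeded, survival_rate, size=wells)
    fracs = np.zeros(wells)
    flags = np.where(survivors == 0, "no-survivors", "")
    pos = survivors > 0
    founders = np.zeros(wells, dtype=np.int64)
    founders[pos] = rng.binomial(survivors[pos], mix_fraction)
    fracs[pos] = founders[pos] / survivors[pos]
    if growth_generations > 0:
        size = survivors.astype(np.int64)
        for _ in range(growth_generations):
            size = size * 2
            counts = np.zeros(wells, dtype=np.int64)
            counts[pos] = rng.binomial(size[pos], fracs[pos])
            fracs[pos] = counts[pos] / size[pos]
    if recorded_events is not None:
        fracs[pos] = rng.binomial(recorded_events, fracs[pos]) / recorded_events
    return pd.DataFrame({
        "well_id": [f"w{i:04d}" for i in range(wells)],
        "seeded": seeded,
        "survivors": survivors,
        "bfp_fraction": fracs,
        "flags": flags,
    })


def multispectral_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Four-color induction cohorts for cross-channel concordance tests.

    A thin wrapper over :func:`fixed_n_cohort` that requires at least
    three label channels (so per-channel estimates can be compared) and
    permits partial labeling (``labeling_efficiency < 1``).
    """
    if len(config.p_channels) < 3:
        raise ValueError("multispectral_cohort requires >= 3 label channels")
    return fixed_n_cohort(config)


def cohort_fractions(table: pd.DataFrame, channel: str = "rfp",
                     drop_flagged: bool = True) -> np.ndarray:
    """Convenience: raw per-animal fraction of ``channel`` from a
    generated table (percent -> proportion), optionally dropping
    flagged rows."""
    df = table
    if drop_flagged and "flags" in df.columns:
        df = df[(df["flags"].isna()) | (df["flags"] == "")]
    return df[f"{channel}_pct"].to_numpy() / 100.0
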