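"""CFSE-dilution proliferation metrics from division-generation counts.

Each cell division halves CFSE intensity, so flow-cytometry gating yields a
count N_i of cells observed in division generation i (i = 0 undivided).
Back-calculating precursor cohorts P_i = N_i / 2^i gives the number of
original cells that account for each generation, from which the five
standard metrics follow:

* % divided        = 100 · Σ_{i≥1} P_i / Σ_i P_i — fraction of the original
  population that divided;
* division index   = Σ i·P_i / Σ P_i — mean divisions per original cell;
* proliferation index = Σ i·P_i / Σ_{i≥1} P_i — mean divisions per cell
  that went into division (≥ 1 when defined);
* expansion index  = Σ N_i / Σ P_i — fold expansion of the whole culture;
* replication index = Σ_{i≥1} N_i / Σ_{i≥1} P_i — fold expansion of the
  responding cells only.

Proliferation and replication indices are undefined (returned as None) when
no cell divided; an explicit marker distinguishes "no responders" from
"no proliferation".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenerationCounts",
    "ProliferationMetrics",
    "proliferation_metrics",
    "simulate_generations",
    "read_counts_csv",
    "metrics_table",
]


@dataclass
class GenerationCounts:
    """Cell counts per CFSE division generation (index 0 = undivided)."""

    counts: tuple[float, ...]
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        counts = tuple(float(c) for c in self.counts)
        if len(counts) == 0:
            raise ValueError("need at least generation 0")
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("at least one generation count must be positive")
        self.counts = counts

    @property
    def precursors(self) -> np.ndarray:
        """Precursor cohorts P_i = N_i / 2^i."""
        n = np.asarray(self.counts, dtype=float)
        return n / 2.0 ** np.arange(len(n))


@dataclass
class ProliferationMetrics:
    percent_divided: float
    division_index: float
    proliferation_index: float | None
    expansion_index: float
    replication_index: float | None


def proliferation_metrics(gc: GenerationCounts) -> ProliferationMetrics:
    """The five precursor-cohort proliferation metrics."""
    n = np.asarray(gc.counts, dtype=float)
    p = gc.precursors
    i = np.arange(len(n))
    p_total = p.sum()
    p_div = p[1:].sum()
    divisions = float((i * p).sum())
    if p_div > 0:
        pi: float | None = divisions / p_div
        ri: float | None = float(n[1:].sum()) / p_div
    else:
        pi = None
        ri = None
    return ProliferationMetrics(
        percent_divided=100.0 * p_div / p_total,
        division_index=divisions / p_total,
        proliferation_index=pi,
        expansion_index=float(n.sum()) / p_total,
        replication_index=ri,
    )


def simulate_generations(
    n_precursors: int,
    p_respond: float,
    divisions_mean: float,
    seed: int = 0,
    max_generations: int = 10,
    sample_id: str = "",
    group: str = "",
) -> GenerationCounts:
    """Seeded precursor-cohort draw for fixture generation.

    Each of ``n_precursors`` cells responds with probability ``p_respond``;
    a responder divides k ≥ 1 times with k ~ Poisson(divisions_mean)
    truncated to k ≥ 1 (and capped at ``max_generations``), contributing
    2^k cells to generation k.  Non-responders stay in generation 0.
    """
    if n_precursors < 1:
        raise ValueError("n_precursors must be >= 1")
    if not 0.0 <= p_respond <= 1.0:
        raise ValueError("p_respond must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    responds = rng.random(n_precursors) < p_respond
    n_resp = int(responds.sum())
    counts = np.zeros(max_generations + 1, dtype=float)
    counts[0] = n_precursors - n_resp
    for _ in range(n_resp):
        k = 0
        while k < 1:
            k = int(rng.poisson(divisions_mean))
        k = min(k, max_generations)
        counts[k] += 2.0**k
    last = int(np.max(np.nonzero(counts)[0])) if counts.any() else 0
    return GenerationCounts(tuple(counts[: last + 1]), sample_id=sample_id, group=group)


def read_counts_csv(path: str | Path) -> list[GenerationCounts]:
    """Read long-format counts (sample_id, group, generation, count)."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "generation", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts CSV must have columns {sorted(required)}")
    out = []
    for (sample, group), sub in df.groupby(["sample_id", "group"], sort=True):
        sub = sub.sort_values("generation")
        gens = sub["generation"].to_numpy()
        counts = np.zeros(int(gens.max()) + 1)
        counts[gens.astype(int)] = sub["count"].to_numpy()
        out.append(GenerationCounts(tuple(counts), sample_id=str(sample), group=str(group)))
    return out


def metrics_table(samples: list[GenerationCounts]) -> pd.DataFrame:
    """One row of the five metrics per sample."""
    rows = []
    for gc in samples:
        m = proliferation_metrics(gc)
        rows.append(
            {
                "sample_id": gc.sample_id,
                "group": gc.group,
                "percent_divided": m.percent_divided,
                "division_index": m.division_index,
                "proliferation_index": m.proliferation_index,
                "expansion_index": m.expansion_index,
                "replication_index": m.replication_index,
            }
        )
    return pd.DataFrame(rows)
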