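"""Transposon-display (TD) statistics for mutation-accumulation lines and
natural isolates.

A TD assay yields, per (line, locus), three replicate above-threshold peak
calls from the same ligated DNA.  Presence requires a replicated peak
(>= ``presence_min_replicates`` of 3); a peak in exactly one replicate is a
*putative somatic insertion* (the DNA pool spans 5-10 individuals, so a
somatic event is not expected in every replicate); no peak is absence.

Rates follow the assay's published units: germline losses are per element per
generation (losses at ancestral loci / ancestral loci / generations), somatic
gains are per element (single-replicate calls at non-ancestral loci / scored
loci).  Treatment comparisons use Welch's unequal-variance t with a one-sided
alternative by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .model import FormatError, ValidationError

logger = logging.getLogger(__name__)

PathType = Union[str, PathLike]

REPLICATE_COLUMNS = ("rep1", "rep2", "rep3")
STATES = ("absent", "putative_somatic", "present")

DEFAULT_GENERATIONS = 45
SEGREGATIONAL_LOSS_PROB = 0.25  # homozygous-absent offspring from a selfed heterozygote


@dataclass
class TDMatrix:
    """Replicate-level presence/absence calls for lines x loci.

    ``data`` columns: line, treatment, locus, rep1, rep2, rep3 (0/1).
    ``generations`` applies to every line (mutation-accumulation designs); it
    is ignored by the population summaries.
    """

    data: pd.DataFrame
    generations: int = DEFAULT_GENERATIONS

    def __post_init__(self) -> None:
        required = {"line", "treatment", "locus", *REPLICATE_COLUMNS}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"TD matrix missing columns: {sorted(missing)}")
        for col in REPLICATE_COLUMNS:
            if self.data[col].isna().any():
                row = self.data[self.data[col].isna()].iloc[0]
                raise ValidationError(
                    f"missing replicate call at line={row['line']!r}, locus={row['locus']!r}"
                )
        dup = self.data.duplicated(subset=["line", "locus"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise ValidationError(
                f"duplicate (line, locus) entry: ({row['line']!r}, {row['locus']!r})"
            )

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    @property
    def loci(self) -> list[str]:
        return sorted(self.data["locus"].unique())

    def treatment_of(self) -> pd.Series:
        return self.data.drop_duplicates("line").set_index("line")["treatment"]

    @classmethod
    def from_tsv(cls, path: PathType, generations: int = DEFAULT_GENERATIONS) -> "TDMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"line": str, "locus": str})
        return cls(df, generations=generations)

    def to_tsv(self, path: PathType) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def call_states(td: TDMatrix, presence_min_replicates: int = 2) -> pd.DataFrame:
    """Collapse replicate calls into one state per (line, locus).

    present: >= ``presence_min_replicates`` of 3 replicates; putative_somatic:
    exactly one replicate; absent: none.  The partition is exhaustive and
    exclusive.
    """
    df = td.data.copy()
    n = df[list(REPLICATE_COLUMNS)].astype(int).sum(axis=1)
    state = np.where(
        n >= presence_min_replicates,
        "present",
        np.where(n == 1, "putative_somatic", "absent"),
    )
    # n == 2 with presence_min_replicates == 3 would otherwise fall through
    state = np.where(
        (n > 1) & (n < presence_min_replicates), "putative_somatic", state
    )
    out = df[["line", "treatment", "locus"]].copy()
    out["n_replicates"] = n
    out["state"] = state
    return out


@dataclass
class RateSummary:
    """Per-line rates with treatment means, standard errors and the Welch
    comparison (one-sided by default) between the first two treatments."""

    per_line: pd.Series
    treatment: pd.Series
    mean: dict[str, float]
    se: dict[str, float]
    n: dict[str, int]
    t: Optional[float] = None
    p: Optional[float] = None
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_line):
            raise ValidationError("rates must be nonnegative")


def _summarize_rates(
    rates: pd.Series,
    treatment: pd.Series,
    order: Sequence[str],
    alternative: str,
) -> RateSummary:
    mean: dict[str, float] = {}
    se: dict[str, float] = {}
    n: dict[str, int] = {}
    groups: dict[str, np.ndarray] = {}
    for tr in order:
        vals = rates[treatment.loc[rates.index] == tr].to_numpy(dtype=float)
        groups[tr] = vals
        n[tr] = len(vals)
        mean[tr] = float(np.mean(vals)) if len(vals) else math.nan
        se[tr] = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan

    t = p = dof = None
    if len(order) >= 2:
        a, b = groups[order[0]], groups[order[1]]
        if len(a) >= 2 and len(b) >= 2:
            res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
            t, p = float(res.statistic), float(res.pvalue)
            dof = float(res.df)
            if not math.isfinite(t):
                t = p = dof = None
        else:
            logger.warning("a treatment has < 2 lines; comparison omitted")
    return RateSummary(
        per_line=rates, treatment=treatment, mean=mean, se=se, n=n, t=t, p=p, df=dof
    )


def _treatment_order(td: TDMatrix, order: Optional[Sequence[str]]) -> list[str]:
    seen = list(dict.fromkeys(td.data["treatment"]))
    if order is None:
        return seen
    unknown = set(order) - set(seen)
    if unknown:
        raise ValidationError(f"treatments not in matrix: {sorted(unknown)}")
    return list(order)


def loss_rate(
    td: TDMatrix,
    ancestral_loci: Iterable[str],
    treatment_order: Optional[Sequence[str]] = None,
    alternative: str = "greater",
    presence_min_replicates: int = 2,
) -> RateSummary:
    """Germline loss rate per element per generation.

    Per line: (ancestral loci scored absent) / (ancestral loci x generations).
    The Welch comparison tests ``treatment_order[0] > treatment_order[1]`` by
    default (losses are expected in selfed lines, not asexuals).
    """
    anc = sorted(set(ancestral_loci))
    if not anc:
        raise ValidationError("no ancestral loci given")
    missing = set(anc) - set(td.loci)
    if missing:
        raise ValidationError(f"ancestral loci absent from matrix: {sorted(missing)}")
    states = call_states(td, presence_min_replicates)
    anc_states = states[states["locus"].isin(anc)]
    losses = (
        anc_states.assign(lost=lambda d: d["state"] == "absent")
        .groupby("line")["lost"]
        .sum()
    )
    rates = losses / (len(anc) * td.generations)
    order = _treatment_order(td, treatment_order)
    return _summarize_rates(rates, td.treatment_of(), order, alternative)


def somatic_gain_rate(
    td: TDMatrix,
    ancestral_loci: Iterable[str],
    treatment_order: Optional[Sequence[str]] = None,
    alternative: str = "greater",
    presence_min_replicates: int = 2,
) -> RateSummary:
    """Putative somatic gain rate per element (no generation scaling).

    Per line: single-replicate calls at non-ancestral loci / scored loci.
    """
    anc = set(ancestral_loci)
    states = call_states(td, presence_min_replicates)
    novel = states[~states["locus"].isin(anc)]
    gains = (
        novel.assign(gain=lambda d: d["state"] == "putative_somatic")
        .groupby("line")["gain"]
        .sum()
        .reindex(td.lines, fill_value=0)
    )
    rates = gains / len(td.loci)
    order = _treatment_order(td, treatment_order)
    return _summarize_rates(rates, td.treatment_of(), order, alternative)


def expected_segregational_losses(
    n_lines: int, loss_prob: float = SEGREGATIONAL_LOSS_PROB
) -> float:
    """Expected losses of a heterozygous insertion across ``n_lines`` selfed
    lines under Mendelian segregation: a selfed Aa parent leaves aa (element
    absent) offspring with probability 1/4."""
    if n_lines < 0:
        raise ValidationError("n_lines must be >= 0")
    if not (0.0 <= loss_prob <= 1.0):
        raise ValidationError("loss_prob must lie in [0, 1]")
    return n_lines * loss_prob


def welch_from_summary(m1: float, se1: float, m2: float, se2: float) -> float:
    """Welch statistic from summary means and standard errors."""
    return (m1 - m2) / math.sqrt(se1 ** 2 + se2 ** 2)


def population_summary(
    td: TDMatrix,
    treatment_order: Optional[Sequence[str]] = None,
    alternative: str = "greater",
    presence_min_replicates: int = 2,
) -> pd.DataFrame:
    """Load and polymorphism summary for natural isolates.

    Per treatment: mean occupied sites per isolate (+/- SE), range, total
    occupied (isolate, locus) pairs, polymorphic loci (occupied in >= 1 but
    not all isolates of the treatment) and singletons (occupied in exactly
    one isolate).  ``attrs`` carry the Welch comparison of per-isolate counts
    between the first two treatments.
    """
    states = call_states(td, presence_min_replicates)
    occupied = states.assign(occ=lambda d: d["state"] == "present")
    per_isolate = occupied.groupby(["treatment", "line"])["occ"].sum()
    order = _treatment_order(td, treatment_order)
    rows = []
    for tr in order:
        counts = per_isolate.loc[tr]
        locus_occ = (
            occupied[occupied["treatment"] == tr].groupby("locus")["occ"].agg(["sum", "count"])
        )
        n_iso = counts.shape[0]
        polymorphic = int(((locus_occ["sum"] >= 1) & (locus_occ["sum"] < n_iso)).sum())
        singletons = int((locus_occ["sum"] == 1).sum())
        rows.append(
            {
                "treatment": tr,
                "n_isolates": n_iso,
                "mean_occupied": float(counts.mean()),
                "se_occupied": float(counts.std(ddof=1) / math.sqrt(n_iso)) if n_iso > 1 else math.nan,
                "min_occupied": int(counts.min()),
                "max_occupied": int(counts.max()),
                "total_occupied": int(counts.sum()),
                "polymorphic_loci": polymorphic,
                "singleton_loci": singletons,
            }
        )
    df = pd.DataFrame(rows)
    if len(order) >= 2:
        a = per_isolate.loc[order[0]].to_numpy(dtype=float)
        b = per_isolate.loc[order[1]].to_numpy(dtype=float)
        if len(a) >= 2 and len(b) >= 2:
            res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
            df.attrs["t"] = float(res.statistic)
            df.attrs["p"] = float(res.pvalue)
            df.attrs["df"] = float(res.df)
    df.attrs["total_occupied_all"] = int(per_isolate.sum())
    return df


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class TDSimConfig:
    """Generating conditions for a mutation-accumulation TD simulation.

    Defaults mirror the assay design this module analyses: 93 lines (46 where
    sex was promoted, 47 where it was prohibited), 7 ancestral loci of which 4
    are heterozygous in the progenitor, ~45 generations, one selfing bout per
    sexual line, and small per-locus somatic-gain rates.
    """

    n_lines: dict = field(default_factory=lambda: {"sexual": 46, "asexual": 47})
    ancestral_loci: int = 7
    het_loci: int = 4
    extra_loci: int = 8
    generations: int = DEFAULT_GENERATIONS
    selfing_loss_prob: float = SEGREGATIONAL_LOSS_PROB
    sexual_bouts: int = 1
    asexual_loss_rate: float = 0.00031  # per element per generation
    somatic_rate: dict = field(default_factory=lambda: {"sexual": 0.0036, "asexual": 0.0016})

    def __post_init__(self) -> None:
        for r in (self.selfing_loss_prob, self.asexual_loss_rate, *self.somatic_rate.values()):
            if not (0.0 <= r <= 1.0):
                raise ValidationError("rates must lie in [0, 1]")
        if self.het_loci > self.ancestral_loci:
            raise ValidationError("het_loci cannot exceed ancestral_loci")

    @property
    def true_loss_rate(self) -> dict:
        """Expected per-line loss rate under the generating process."""
        p_sex = 1.0 - (1.0 - self.selfing_loss_prob) ** self.sexual_bouts
        return {
            "sexual": self.het_loci * p_sex / (self.ancestral_loci * self.generations),
            "asexual": self.asexual_loss_rate,
        }

    @property
    def true_somatic_rate(self) -> dict:
        return dict(self.somatic_rate)


def simulate_td(config: TDSimConfig | None = None, seed: int = 0):
    """Simulate a replicate-level TD matrix with a truth manifest.

    Heterozygous ancestral loci are lost with probability
    ``selfing_loss_prob`` per sexual bout (sexual lines only); asexual lines
    lose ancestral loci at ``asexual_loss_rate`` per generation; somatic
    gains appear as single-replicate calls at non-ancestral loci, with the
    per-line event count Binomial(scored loci, rate).  Fully deterministic
    under ``seed``.
    """
    config = config or TDSimConfig()
    rng = np.random.default_rng(seed)
    anc = [f"anc{i+1}" for i in range(config.ancestral_loci)]
    het = set(anc[: config.het_loci])
    extra = [f"new{i+1}" for i in range(config.extra_loci)]
    loci = anc + extra
    n_scored = len(loci)
    rows = []
    events = []
    p_self = 1.0 - (1.0 - config.selfing_loss_prob) ** config.sexual_bouts
    p_asex = min(1.0, config.asexual_loss_rate * config.generations)
    for treatment, n in config.n_lines.items():
        for li in range(n):
            line = f"{treatment[:3]}_{li+1:03d}"
            present = {}
            for locus in anc:
                if treatment == "sexual":
                    lost = locus in het and rng.random() < p_self
                else:
                    lost = rng.random() < p_asex
                present[locus] = not lost
                if lost:
                    events.append({"line": line, "locus": locus, "type": "loss"})
            for locus in extra:
                present[locus] = False
            rate = config.somatic_rate.get(treatment, 0.0)
            n_gains = rng.binomial(n_scored, rate)
            gain_loci = list(
                rng.choice(extra, size=min(n_gains, len(extra)), replace=False)
            )
            for locus in loci:
                if present[locus]:
                    reps = [1, 1, 1]
                elif locus in gain_loci:
                    reps = [0, 0, 0]
                    reps[int(rng.integers(0, 3))] = 1
                    events.append({"line": line, "locus": locus, "type": "somatic_gain"})
                else:
                    reps = [0, 0, 0]
                rows.append(
                    {
                        "line": line,
                        "treatment": treatment,
                        "locus": locus,
                        "rep1": reps[0],
                        "rep2": reps[1],
                        "rep3": reps[2],
                    }
                )
    td = TDMatrix(pd.DataFrame(rows), generations=config.generations)
    manifest = {
        "ancestral_loci": anc,
        "heterozygous_loci": sorted(het),
        "extra_loci": extra,
        "events": events,
        "true_loss_rate": config.true_loss_rate,
        "true_somatic_rate": config.true_somatic_rate,
        "seed": seed,
    }
    return td, manifest
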