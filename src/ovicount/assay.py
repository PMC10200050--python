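"""Plant-insect resistance statistics from clip-cage whitefly assays.

In a no-choice assay, two clip-on cages with five one-day-old female
whiteflies each are attached to leaves of every plant (three plants per
accession).  Five days later two quantities are scored per cage: the number
of females still alive and the number of eggs laid (counted on images from
one or more devices).  Per plant (cages pooled):

* adult survival       AS = alive / total released            (in [0, 1])
* oviposition rate     OR = 2 * eggs / (alive + released)     (eggs per
  female per 5 days; the denominator is the average of the initial and the
  surviving number of females, times two)

AS is arcsine-square-root transformed and OR square-root transformed before
group comparison, the standard variance-stabilizing transforms for a
proportion and a count rate.  Susceptible and resistant accessions are
compared with two-sample t-tests (equal-variance Student's by default,
Welch's optionally) on the transformed per-plant values.

"Total whiteflies" is the number released (five per cage): some cages
recover fewer than five insects (alive + dead < released), so the released
number is the only unambiguous denominator.

A transcription of the reference assay table ships with the package
(``data/table2_whitefly_assay.csv``).  Two of its cells are flattened
ambiguously in the source and are transcribed on a best-effort basis
(BER481-3 plant 1 cage 1 egg counts; Moneymaker plant 3 cage 1 AutoEnto
count); neither affects any 0.05-level conclusion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEVICES",
    "DEFAULT_COMPARISON_PLAN",
    "AssayRecord",
    "ComparisonResult",
    "adult_survival",
    "oviposition_rate",
    "arcsine_sqrt",
    "load_assay_table",
    "summarize_plants",
    "compare_accessions",
    "resistance_report",
    "comparisons_to_frame",
]

logger = logging.getLogger(__name__)

DEVICES = {"vhx7000": "eggs_vhx7000", "autoento": "eggs_autoento"}

#: (susceptible, resistant) accession pairs within each crop:
#: cultivated tomato vs wild tomato, cultivated potato vs wild potato.
DEFAULT_COMPARISON_PLAN: tuple[tuple[str, str], ...] = (
    ("Moneymaker", "LA1777"),
    ("RH89-039-16", "BER481-3"),
)

RECORD_COLUMNS = [
    "species", "accession", "plant", "cage", "alive", "dead",
    "eggs_vhx7000", "eggs_autoento",
]


@dataclass(frozen=True)
class AssayRecord:
    """One clip cage on one plant."""

    species: str
    accession: str
    plant: int
    cage: int
    alive: int
    dead: int
    eggs_by_device: dict[str, int]
    released: int = 5

    def __post_init__(self) -> None:
        if self.alive < 0 or self.dead < 0 or self.released < 1:
            raise ValueError("counts must be non-negative, released positive")


def adult_survival(alive: int, total: int) -> float:
    """Fraction of released females alive at assay end."""
    if total < 1:
        raise ValueError("total whiteflies must be positive")
    if not (0 <= alive <= total):
        raise ValueError(f"alive ({alive}) must be in [0, total={total}]")
    return alive / total


def oviposition_rate(eggs: int, alive: int, total: int) -> float:
    """Eggs per female per assay period: 2*eggs / (alive + total)."""
    if total < 1:
        raise ValueError("total whiteflies must be positive")
    if not (0 <= alive <= total):
        raise ValueError(f"alive ({alive}) must be in [0, total={total}]")
    if eggs < 0:
        raise ValueError("eggs must be non-negative")
    return 2.0 * eggs / (alive + total)


def arcsine_sqrt(proportion: float) -> float:
    """Variance-stabilizing transform for a proportion: arcsin(sqrt(p))."""
    if not (0 <= proportion <= 1):
        raise ValueError("proportion must lie in [0, 1]")
    return math.asin(math.sqrt(proportion))


def load_assay_table(path=None) -> pd.DataFrame:
    """Load cage-level assay records (packaged reference table by default)."""
    if path is None:
        with resources.files("ovicount.data").joinpath(
            "table2_whitefly_assay.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns {sorted(missing)}")
    return df


def summarize_plants(
    records: pd.DataFrame, device: str, released_per_cage: int = 5
) -> pd.DataFrame:
    """Pool cages per plant and compute AS, OR, and their transforms.

    Returns one row per (accession, plant) with columns ``adult_survival``,
    ``oviposition_rate``, ``transformed_as``, ``transformed_or``.  Cages
    where alive + dead differs from the released number are kept but logged.
    """
    if device not in DEVICES:
        raise ValueError(
            f"unknown device {device!r}; available devices: {', '.join(sorted(DEVICES))}"
        )
    egg_col = DEVICES[device]
    odd = records[records["alive"] + records["dead"] != released_per_cage]
    for row in odd.itertuples(index=False):
        logger.warning(
            "accession %s plant %s cage %s: alive+dead = %d != released %d",
            row.accession, row.plant, row.cage, row.alive + row.dead, released_per_cage,
        )
    rows = []
    for (species, accession, plant), grp in records.groupby(
        ["species", "accession", "plant"], sort=False
    ):
        alive = int(grp["alive"].sum())
        released = released_per_cage * len(grp)
        eggs = int(grp[egg_col].sum())
        as_ = adult_survival(alive, released)
        or_ = oviposition_rate(eggs, alive, released)
        rows.append(
            {
                "species": species,
                "accession": accession,
                "plant": plant,
                "n_cages": len(grp),
                "alive": alive,
                "released": released,
                "eggs": eggs,
                "adult_survival": as_,
                "oviposition_rate": or_,
                "transformed_as": arcsine_sqrt(as_),
                "transformed_or": math.sqrt(or_),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample t-test between accessions on a transformed metric."""

    accession_a: str
    accession_b: str
    metric: str  # "as" or "or"
    device: str | None
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    equal_var: bool

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_value < 0.01

    @property
    def significant_001(self) -> bool:
        return self.p_value < 0.001


_METRIC_COLUMNS = {"as": "transformed_as", "or": "transformed_or"}


def compare_accessions(
    summaries: pd.DataFrame,
    accession_a: str,
    accession_b: str,
    metric: str = "as",
    device: str | None = None,
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sided two-sample t-test on transformed per-plant values."""
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLUMNS)}")
    col = _METRIC_COLUMNS[metric]
    a = summaries.loc[summaries["accession"] == accession_a, col].to_numpy(float)
    b = summaries.loc[summaries["accession"] == accession_b, col].to_numpy(float)
    for name, vals in ((accession_a, a), (accession_b, b)):
        if vals.size == 0:
            raise ValueError(f"accession {name!r} absent from summaries")
        if vals.size < 2:
            raise ValueError(f"accession {name!r} has fewer than 2 plants")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError(
            "zero within-group variance in both groups; a t-test is not "
            "meaningful here — compare the groups exactly instead"
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        accession_a=accession_a,
        accession_b=accession_b,
        metric=metric,
        device=device,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        equal_var=equal_var,
    )


def resistance_report(
    records: pd.DataFrame,
    device: str,
    plan: Sequence[tuple[str, str]] = DEFAULT_COMPARISON_PLAN,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Per-plant summaries plus AS and OR comparisons for each planned pair.

    ``plan`` pairs a susceptible with a resistant accession within each crop.
    Adult survival uses no egg counts and is therefore device-independent;
    oviposition uses the selected device's counts.
    """
    summaries = summarize_plants(records, device)
    present = set(summaries["accession"])
    comparisons: list[ComparisonResult] = []
    for metric in ("as", "or"):
        for susceptible, resistant in plan:
            for acc in (susceptible, resistant):
                if acc not in present:
                    raise ValueError(f"accession {acc!r} absent from records")
            comparisons.append(
                compare_accessions(
                    summaries, susceptible, resistant, metric=metric,
                    device=device, equal_var=equal_var,
                )
            )
    return summaries, comparisons


def comparisons_to_frame(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": c.metric,
                "device": c.device,
                "accession_a": c.accession_a,
                "accession_b": c.accession_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "t_statistic": c.t_statistic,
                "p_value": c.p_value,
                "significant_05": c.significant_05,
                "significant_01": c.significant_01,
                "significant_001": c.significant_001,
            }
            for c in comparisons
        ]
    )
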