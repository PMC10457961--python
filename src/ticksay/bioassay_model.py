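"""Adult immersion test (AIT) domain model and Drummond efficacy indices.

The adult immersion test scores engorged female cattle ticks after immersion
in a conidial suspension: survival at day 15, visible mycelial growth
(morbidity), oviposited egg mass, and hatching of the resulting egg mass.
From those raw observations the classic Drummond indices are derived:

* mortality % and morbidity % — fractions of the experimental unit;
* EPI% (egg production index) — egg mass as a percentage of the female's
  initial body mass;
* EC% (eclosion) — percentage of eggs that hatched;
* IO% / IH% / REI% — percent inhibition of oviposition, hatching and
  estimated reproduction relative to the untreated control;
* RE — estimated larvae per female, ``(EPI%/100) x (EC%/100) x 20000``,
  using Drummond's larvae-per-gram convention constant 20000.

Two averaging semantics are supported when summarising a whole bioassay
(:func:`efficacy_table`): computing every index per replicate and averaging
(the default, which reproduces published AIT tables), or computing the
inhibition indices once from the group mean columns ("pooled").  The two
legitimately differ because a mean of ratios is not a ratio of means.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REPRODUCTION_CONSTANT",
    "CONTROL_LABEL",
    "TickRecord",
    "ReplicateIndices",
    "EfficacyTable",
    "mortality_pct",
    "morbidity_pct",
    "epi_pct",
    "ec_pct",
    "inhibition_pct",
    "re_value",
    "efficacy_table",
]

logger = logging.getLogger(__name__)

#: Drummond's larvae-per-gram projection constant (larvae per female ceiling).
REPRODUCTION_CONSTANT = 20000.0

#: Canonical label of the untreated group.
CONTROL_LABEL = "control"

#: Index columns of an efficacy table, in reporting order.
INDEX_COLUMNS = (
    "mortality_pct",
    "morbidity_pct",
    "epi_pct",
    "io_pct",
    "ec_pct",
    "ih_pct",
    "re_value",
    "rei_pct",
)


@dataclass(frozen=True)
class TickRecord:
    """One engorged female's observed outcomes in the adult immersion test.

    Parameters
    ----------
    tick_id:
        Opaque identifier, unique within a dataset.
    group:
        Dose label: ``"control"`` or a conidia/mL concentration rendered as a
        number (e.g. ``"1e7"``).
    replicate:
        1-based replicate (experimental unit) number.
    initial_mass:
        Engorged female weight after washing, mg (> 0).
    dead:
        Vital status at day 15 of incubation.
    morbid:
        Visible mycelial growth on the cuticle.  Independent of ``dead``:
        a dead tick overgrown by the fungus counts in both tallies.
    egg_mass:
        Oviposited egg mass, mg (>= 0).
    hatched, unhatched:
        Larval / unhatched egg counts from the incubated egg mass.
    """

    tick_id: str
    group: str
    replicate: int
    initial_mass: float
    dead: bool
    morbid: bool
    egg_mass: float
    hatched: int
    unhatched: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"{self.tick_id}: replicate must be >= 1")
        if not self.initial_mass > 0:
            raise ValueError(f"{self.tick_id}: initial_mass must be > 0 mg")
        if self.egg_mass < 0:
            raise ValueError(f"{self.tick_id}: egg_mass must be >= 0 mg")
        if self.hatched < 0 or self.unhatched < 0:
            raise ValueError(f"{self.tick_id}: egg counts must be >= 0")
        if self.egg_mass == 0 and (self.hatched or self.unhatched):
            raise ValueError(
                f"{self.tick_id}: egg counts present but egg_mass is 0"
            )


@dataclass(frozen=True)
class ReplicateIndices:
    """Drummond indices evaluated on one experimental unit (replicate).

    ``ec_pct`` (and hence ``ih_pct``, ``re_value``, ``rei_pct``) is NaN when
    no tick in the replicate oviposited — eclosion is undefined, not zero.
    ``io_pct``/``ih_pct``/``rei_pct`` may be negative (treatment above
    control) and are never clamped.
    """

    group: str
    replicate: int
    n_ticks: int
    mortality_pct: float
    morbidity_pct: float
    epi_pct: float
    ec_pct: float
    io_pct: float = math.nan
    ih_pct: float = math.nan
    re_value: float = math.nan
    rei_pct: float = math.nan


@dataclass
class EfficacyTable:
    """Per-group mean ± sample SD of each efficacy index.

    Attributes
    ----------
    table:
        DataFrame indexed by group label (control first, then doses in input
        order) with ``<index>_mean`` / ``<index>_sd`` columns for every entry
        of :data:`INDEX_COLUMNS`, plus ``n_ticks``.
    averaging_mode:
        ``"per-replicate"`` or ``"pooled"`` (see :func:`efficacy_table`).
    replicates:
        The per-replicate index values the table was computed from.
    """

    table: pd.DataFrame
    averaging_mode: str
    replicates: list[ReplicateIndices] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        return list(self.table.index)

    def to_csv(self, path) -> None:
        """Write the table in the documented CSV dialect."""
        self.table.to_csv(path, index_label="group", float_format="%.6g")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(float_format=lambda v: f"{v:.2f}")


# ---------------------------------------------------------------------------
# Elementary indices
# ---------------------------------------------------------------------------


def mortality_pct(records: Iterable[TickRecord]) -> float:
    """Percent dead females: ``100 x dead / total``."""
    records = list(records)
    if not records:
        raise ValueError("no ticks in unit")
    return 100.0 * sum(r.dead for r in records) / len(records)


def morbidity_pct(records: Iterable[TickRecord]) -> float:
    """Percent females with visible mycelial growth: ``100 x sick / total``.

    Counted independently of vital status.
    """
    records = list(records)
    if not records:
        raise ValueError("no ticks in unit")
    return 100.0 * sum(r.morbid for r in records) / len(records)


def epi_pct(egg_mass: float, initial_mass: float) -> float:
    """Egg production index: ``100 x egg mass / initial body mass`` (both mg)."""
    if not initial_mass > 0:
        raise ValueError("initial_mass must be > 0 mg")
    if egg_mass < 0:
        raise ValueError("egg_mass must be >= 0 mg")
    return 100.0 * egg_mass / initial_mass


def ec_pct(hatched: int, unhatched: int) -> float:
    """Eclosion percentage: ``100 x hatched / (hatched + unhatched)``.

    Returns NaN (undefined, deliberately distinct from 0) when there are no
    eggs at all: a tick that laid nothing has no hatching success to report.
    """
    if hatched < 0 or unhatched < 0:
        raise ValueError("egg counts must be >= 0")
    total = hatched + unhatched
    if total == 0:
        return math.nan
    return 100.0 * hatched / total


def inhibition_pct(control_value: float, treatment_value: float) -> float:
    """Percent inhibition relative to control: ``100 x (c - t) / c``.

    Shared form of IO%, IH% and REI%.  Negative when the treatment exceeds
    the control; never clamped.
    """
    if control_value == 0:
        raise ValueError("inhibition undefined for zero control")
    return 100.0 * (control_value - treatment_value) / control_value


def re_value(epi: float, ec: float) -> float:
    """Estimated reproduction: ``(EPI%/100) x (EC%/100) x 20000`` larvae."""
    if epi < 0:
        raise ValueError("epi_pct must be >= 0")
    if not 0 <= ec <= 100 and not math.isnan(ec):
        raise ValueError("ec_pct must lie in [0, 100]")
    return (epi / 100.0) * (ec / 100.0) * REPRODUCTION_CONSTANT


# ---------------------------------------------------------------------------
# Whole-bioassay summary
# ---------------------------------------------------------------------------


def _replicate_base_indices(
    group: str, replicate: int, records: Sequence[TickRecord]
) -> ReplicateIndices:
    """Mortality/morbidity/EPI/EC for one experimental unit.

    EPI is the unweighted mean of per-tick EPI values (every tick counts,
    non-ovipositers as 0).  EC aggregates the egg counts of all ovipositing
    ticks of the replicate, and is NaN when none oviposited.
    """
    epis = [epi_pct(r.egg_mass, r.initial_mass) for r in records]
    hatched = sum(r.hatched for r in records)
    unhatched = sum(r.unhatched for r in records)
    if hatched + unhatched == 0:
        logger.warning(
            "group %s replicate %d: no ovipositing ticks, EC undefined",
            group,
            replicate,
        )
        ec = math.nan
    else:
        ec = ec_pct(hatched, unhatched)
    return ReplicateIndices(
        group=group,
        replicate=replicate,
        n_ticks=len(records),
        mortality_pct=mortality_pct(records),
        morbidity_pct=morbidity_pct(records),
        epi_pct=float(np.mean(epis)),
        ec_pct=ec,
    )


def _nanmean(values: Sequence[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def _nansd(values: Sequence[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    if len(vals) < 2:
        return math.nan
    return float(np.std(vals, ddof=1))


def efficacy_table(
    dataset: Iterable[TickRecord],
    averaging_mode: str = "per-replicate",
    control_label: str = CONTROL_LABEL,
) -> EfficacyTable:
    """Summarise a bioassay into a per-group efficacy index table.

    Parameters
    ----------
    dataset:
        Tick records covering a control group and one or more treatments.
    averaging_mode:
        ``"per-replicate"`` (default): every index is evaluated on each
        replicate — the inhibition indices against the *control group mean*
        EPI/EC/RE — and the table reports mean ± sample SD across replicates.
        By construction the control row's IO/IH/REI mean is 0 with a nonzero
        SD.  ``"pooled"``: the base columns are identical, but IO/IH/REI are
        computed once per group from group-pooled tallies (total egg mass /
        total body mass, total hatched / total eggs); their SD is undefined.
        The modes agree on mortality, morbidity, EPI, EC and RE and
        generally disagree on the inhibition indices, because a mean of
        per-replicate ratios is not a ratio of pooled tallies.
    control_label:
        Label identifying the untreated group.

    Raises
    ------
    ValueError
        If the dataset is empty, has no control group, or the mode is
        unknown.  Replicates without any ovipositing tick get NaN EC and are
        excluded from EC/IH/RE/REI means with a logged warning.
    """
    if averaging_mode not in ("per-replicate", "pooled"):
        raise ValueError(f"unknown averaging_mode {averaging_mode!r}")
    records = list(dataset)
    if not records:
        raise ValueError("empty bioassay dataset")

    units: dict[tuple[str, int], list[TickRecord]] = defaultdict(list)
    group_order: list[str] = []
    for rec in records:
        if rec.group not in group_order:
            group_order.append(rec.group)
        units[(rec.group, rec.replicate)].append(rec)
    if control_label not in group_order:
        raise ValueError(f"missing control group {control_label!r}")
    group_order = [control_label] + [g for g in group_order if g != control_label]

    base = {
        key: _replicate_base_indices(key[0], key[1], recs)
        for key, recs in sorted(units.items(), key=lambda kv: kv[0][1])
    }

    # Control baselines (means over control replicates).
    ctrl = [b for b in base.values() if b.group == control_label]
    ctrl_epi = _nanmean([b.epi_pct for b in ctrl])
    ctrl_ec = _nanmean([b.ec_pct for b in ctrl])
    ctrl_re = _nanmean(
        [re_value(b.epi_pct, b.ec_pct) for b in ctrl if not math.isnan(b.ec_pct)]
    )

    replicates: list[ReplicateIndices] = []
    for b in base.values():
        re_rep = (
            re_value(b.epi_pct, b.ec_pct) if not math.isnan(b.ec_pct) else math.nan
        )
        replicates.append(
            ReplicateIndices(
                group=b.group,
                replicate=b.replicate,
                n_ticks=b.n_ticks,
                mortality_pct=b.mortality_pct,
                morbidity_pct=b.morbidity_pct,
                epi_pct=b.epi_pct,
                ec_pct=b.ec_pct,
                io_pct=inhibition_pct(ctrl_epi, b.epi_pct),
                ih_pct=(
                    inhibition_pct(ctrl_ec, b.ec_pct)
                    if not math.isnan(b.ec_pct)
                    else math.nan
                ),
                re_value=re_rep,
                rei_pct=(
                    inhibition_pct(ctrl_re, re_rep)
                    if not math.isnan(re_rep)
                    else math.nan
                ),
            )
        )

    rows = []
    for group in group_order:
        reps = [r for r in replicates if r.group == group]
        row: dict[str, float] = {"n_ticks": sum(r.n_ticks for r in reps)}
        for col in INDEX_COLUMNS:
            vals = [getattr(r, col) for r in reps]
            row[f"{col}_mean"] = _nanmean(vals)
            row[f"{col}_sd"] = _nansd(vals)
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(group_order, name="group"))

    if averaging_mode == "pooled":
        # IO/IH/REI once per group from group-pooled tallies: EPI as total
        # egg mass over total body mass, EC as total hatched over total eggs,
        # RE from those two.  A mean of per-replicate ratios is not a ratio
        # of pooled tallies, so these legitimately differ from the
        # per-replicate inhibition columns.
        pooled_vals: dict[str, tuple[float, float, float]] = {}
        for group in group_order:
            recs = [r for r in records if r.group == group]
            epi_pool = epi_pct(
                sum(r.egg_mass for r in recs), sum(r.initial_mass for r in recs)
            )
            ec_pool = ec_pct(
                sum(r.hatched for r in recs), sum(r.unhatched for r in recs)
            )
            re_pool = (
                re_value(epi_pool, ec_pool) if not math.isnan(ec_pool) else math.nan
            )
            pooled_vals[group] = (epi_pool, ec_pool, re_pool)
        ctrl_pool = pooled_vals[control_label]
        for i, col in enumerate(("io_pct", "ih_pct", "rei_pct")):
            table[f"{col}_mean"] = [
                (
                    inhibition_pct(ctrl_pool[i], pooled_vals[g][i])
                    if not math.isnan(pooled_vals[g][i])
                    else math.nan
                )
                for g in group_order
            ]
            table[f"{col}_sd"] = math.nan

    return EfficacyTable(table=table, averaging_mode=averaging_mode, replicates=replicates)
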