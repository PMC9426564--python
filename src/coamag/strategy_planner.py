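"""Expansion of the four assembly-binning strategies into executable plans.

The four strategies combine {single assembly, coassembly} with
{single-binning, cobinning}:

* SASB — one assembly unit per sample; each sample maps only to its own unit.
* SACB — one unit per sample; every sample maps to every unit (N² jobs —
  the cost of computing co-abundance across the whole dataset).
* CASB — one unit per coassembly group; each sample maps to its group's unit.
* CACB — one unit per group; every sample maps to every unit (N·G jobs).

The plan is a contract for an external executor (assembler + aligner +
binner); nothing is run here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .coassembly_clustering import CoassemblyPlan
from .io_formats import SampleRecord, _open_text


class Strategy(str, enum.Enum):
    SASB = "SASB"  # single-assembly, single-binning
    SACB = "SACB"  # single-assembly, cobinning
    CASB = "CASB"  # coassembly, single-binning
    CACB = "CACB"  # coassembly, cobinning

    @property
    def is_coassembly(self) -> bool:
        return self in (Strategy.CASB, Strategy.CACB)

    @property
    def is_cobinning(self) -> bool:
        return self in (Strategy.SACB, Strategy.CACB)


@dataclass(frozen=True)
class AssemblyUnit:
    """One assembly job: a unit id plus its member sample(s)."""

    unit_id: str
    member_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_samples:
            raise ValueError(f"assembly unit {self.unit_id!r} has no members")
        if len(set(self.member_samples)) != len(self.member_samples):
            raise ValueError(f"assembly unit {self.unit_id!r} has duplicate members")


@dataclass
class StrategyPlan:
    """Assembly units plus the (sample, unit) read-mapping jobs of a strategy."""

    strategy: Strategy
    assembly_units: list[AssemblyUnit]
    mapping_jobs: list[tuple[str, str]]  # (sample_id, unit_id), sorted unique


def plan_strategy(
    samples: Sequence[SampleRecord | str],
    coassembly: CoassemblyPlan | None,
    strategy: Strategy | str,
) -> StrategyPlan:
    """Expand samples (and a coassembly plan for CA strategies) into a plan.

    Job counts follow from the definitions: SASB -> N, SACB -> N²,
    CASB -> Σ_g |g| = N, CACB -> N·G.
    """
    strategy = Strategy(strategy)
    sample_ids = [s.sample_id if isinstance(s, SampleRecord) else s for s in samples]
    if not sample_ids:
        raise ValueError("empty sample list")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")

    if strategy.is_coassembly:
        if coassembly is None:
            raise ValueError(f"strategy {strategy.value} requires a coassembly plan")
        if sorted(coassembly.sample_ids) != sorted(sample_ids):
            raise ValueError("coassembly plan does not partition the sample set")
        units = [
            AssemblyUnit(unit_id=f"coasm_{gid}", member_samples=tuple(members))
            for gid, members in sorted(coassembly.groups.items())
        ]
    else:
        units = [AssemblyUnit(unit_id=f"single_{sid}", member_samples=(sid,))
                 for sid in sample_ids]

    if strategy.is_cobinning:
        jobs = {(sid, u.unit_id) for sid in sample_ids for u in units}
    else:
        jobs = {(sid, u.unit_id) for u in units for sid in u.member_samples}

    return StrategyPlan(
        strategy=strategy,
        assembly_units=units,
        mapping_jobs=sorted(jobs),
    )


def emit_plan(plan: StrategyPlan, path) -> None:
    """Write <path>.units.tsv and <path>.jobs.tsv (stable sort order)."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    with _open_text(base.with_suffix(base.suffix + ".units.tsv"), "wt") as out:
        out.write("strategy\tunit_id\tmember_samples\n")
        for unit in sorted(plan.assembly_units, key=lambda u: u.unit_id):
            out.write(f"{plan.strategy.value}\t{unit.unit_id}\t"
                      f"{';'.join(unit.member_samples)}\n")
    with _open_text(base.with_suffix(base.suffix + ".jobs.tsv"), "wt") as out:
        out.write("strategy\tsample_id\tunit_id\n")
        for sid, uid in plan.mapping_jobs:
            out.write(f"{plan.strategy.value}\t{sid}\t{uid}\n")


def read_plan(path) -> StrategyPlan:
    """Read back a plan written by :func:`emit_plan` (round-trip inverse)."""
    base = Path(path)
    units: list[AssemblyUnit] = []
    strategy: str | None = None
    with _open_text(base.with_suffix(base.suffix + ".units.tsv")) as handle:
        next(handle)
        for line in handle:
            strat, uid, members = line.rstrip("\n").split("\t")
            strategy = strat
            units.append(AssemblyUnit(unit_id=uid, member_samples=tuple(members.split(";"))))
    jobs: list[tuple[str, str]] = []
    with _open_text(base.with_suffix(base.suffix + ".jobs.tsv")) as handle:
        next(handle)
        for line in handle:
            _, sid, uid = line.rstrip("\n").split("\t")
            jobs.append((sid, uid))
    if strategy is None:
        raise ValueError(f"{base}: empty plan")
    return StrategyPlan(strategy=Strategy(strategy), assembly_units=units,
                        mapping_jobs=sorted(set(jobs)))
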