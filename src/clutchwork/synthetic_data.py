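"""Ground-truth synthetic colony data.

The raw per-animal records behind the published summary tables were never
deposited, so every pipeline stage here is exercised against synthetic
records generated from the printed moments instead. A
:class:`GroundTruthDataset` carries both views of the same events — the
fully attributed individual records (with true clutch indices) and the
anonymized cohort log — so that the cohort round-inference rule can be
scored against known truth, something impossible with real cohort data.

Presets (``make_params``) reproduce the five published table blocks:

========================  =======================================================
``hro_isolated``          16 *H. robusta* reared in isolation (snail diet)
``hro_cohort``            interbreeding cohort of 48 *H. robusta* (snail diet)
``hoc_isolated``          5 *H. octatestisaca* in isolation (bloodworm diet)
``hau_cohort23``          interbreeding cohort of 23 *H. austinensis*
``hau_cohort60``          interbreeding cohort of 60 *H. austinensis*
========================  =======================================================

Under the simulator's no-interaction null, the true round of a clutch is
simply its within-parent clutch index; no hidden coordination model is ever
injected. Users wanting a "coordinated" alternative must construct it
explicitly by offsetting days.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

from .lifehist import ClutchNumberStats
from .mc_simulator import (
    DistSpec,
    SimParams,
    categorical_from_survival_counts,
    simulate_records,
)
from .records_io import (
    ClutchEvent,
    CohortLog,
    IndividualRecord,
    write_cohort_log,
    write_individual_records,
)

__all__ = [
    "PRESETS",
    "GroundTruthDataset",
    "make_params",
    "preset_table",
    "generate_dataset",
    "inject_deaths",
    "misassignment_rate",
]

PRESETS = (
    "hro_isolated",
    "hro_cohort",
    "hoc_isolated",
    "hau_cohort23",
    "hau_cohort60",
)


def _load_preset(name: str) -> dict:
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESETS)}"
        )
    ref = importlib.resources.files("clutchwork") / "presets" / f"{name}.json"
    return json.loads(ref.read_text(encoding="utf-8"))


def make_params(preset: str) -> SimParams:
    """Simulator parameters populated from a published table block.

    The clutch-count categorical is derived from the block's per-index
    sample sizes S_1..S_K (see
    :func:`~clutchwork.mc_simulator.categorical_from_survival_counts`).
    """
    obj = _load_preset(preset)
    return SimParams(
        label=obj["label"],
        zd_c1=DistSpec.from_json(obj["zd_c1"]),
        inter_clutch=[DistSpec.from_json(d) for d in obj["inter_clutch"]],
        clutch_size=[DistSpec.from_json(d) for d in obj["clutch_size"]],
        clutch_count=categorical_from_survival_counts(
            obj["s_counts"], obj["n_individuals"]
        ),
        post_last_survival=DistSpec.from_json(obj["post_last_survival"]),
        lifespan=DistSpec.from_json(obj["lifespan"]),
        notes=dict(obj.get("notes", {})),
    )


def preset_table(preset: str) -> tuple[list[ClutchNumberStats], int]:
    """The printed per-clutch-index size table of a preset block.

    Returns the rows (index, sample size S, mean, SD, min, max) and N, the
    number of individuals in the block — the inputs needed to reconstruct
    reproductive capacity from a printed table alone.
    """
    obj = _load_preset(preset)
    rows = [
        ClutchNumberStats(
            k=k,
            n=s,
            mean=float(d["mean"]),
            sd=(float(d["sd"]) if s > 1 else None),
            min=d["min"],
            max=d["max"],
        )
        for k, (s, d) in enumerate(zip(obj["s_counts"], obj["clutch_size"]), start=1)
    ]
    return rows, int(obj["n_individuals"])


@dataclass
class GroundTruthDataset:
    """Individual records and the matching anonymized cohort log.

    ``true_labels`` is parallel to ``cohort.clutches`` (day order, stable
    ties) and holds each clutch's true index within its parent — the round
    it belongs to under the no-interaction null.
    """

    params: SimParams
    records: list[IndividualRecord]
    cohort: CohortLog
    true_labels: list[int]
    seed: int

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Write individuals.csv, cohort.csv(+.json), truth.json, params.json.

        Deterministic: the same dataset always produces byte-identical files.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "individuals": outdir / "individuals.csv",
            "cohort": outdir / "cohort.csv",
            "truth": outdir / "truth.json",
            "params": outdir / "params.json",
        }
        write_individual_records(self.records, paths["individuals"])
        write_cohort_log(self.cohort, paths["cohort"])
        paths["truth"].write_text(
            json.dumps(
                {"seed": self.seed, "true_labels": self.true_labels}, indent=2
            )
            + "\n",
            encoding="utf-8",
        )
        self.params.save(paths["params"])
        return paths


def _anonymize(
    records: Sequence[IndividualRecord], label: str
) -> tuple[CohortLog, list[int]]:
    """Merge records into a cohort log, carrying true clutch indices along
    through the same stable day sort build_pseudo_cohort uses."""
    decorated = [
        (c.day, ClutchEvent(day=c.day, size=c.size), k)
        for rec in records
        for k, c in enumerate(rec.clutches, start=1)
    ]
    decorated.sort(key=lambda t: t[0])  # stable
    deaths = sorted(
        r.death_day for r in records if not r.censored and r.death_day is not None
    )
    log = CohortLog(
        n0=len(records),
        death_days=deaths,
        clutches=[e for _, e, _ in decorated],
        label=label,
    )
    return log, [k for _, _, k in decorated]


def generate_dataset(
    params: SimParams,
    n: int,
    seed: int,
    outdir: Optional[Union[str, Path]] = None,
) -> GroundTruthDataset:
    """Simulate a colony of ``n`` individuals with ground truth attached.

    Reproducible: the same (params, n, seed) yields the same dataset, and
    ``outdir`` writes are byte-identical across calls.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    records = simulate_records(params, n, seed)
    cohort, labels = _anonymize(records, label=f"synthetic:{params.label}")
    ds = GroundTruthDataset(
        params=params, records=records, cohort=cohort, true_labels=labels, seed=seed
    )
    if outdir is not None:
        ds.write(outdir)
    return ds


def inject_deaths(
    dataset: GroundTruthDataset, schedule: Sequence[tuple[str, int]]
) -> GroundTruthDataset:
    """Impose early deaths and rebuild the cohort log.

    Each (individual id, death day) entry truncates that animal's record:
    clutches after the death day are removed (a clutch on the death day
    itself stands — animals are counted present on their recorded death
    day). Ground-truth labels are recomputed for the surviving clutches, so
    the misassignment a premature death forces on the round-counting rule
    stays measurable. An empty schedule returns an equivalent dataset.
    """
    by_id = {r.id: r for r in dataset.records}
    for rid, day in schedule:
        if rid not in by_id:
            raise ValueError(f"unknown individual id {rid!r}")
        if day < 0:
            raise ValueError(f"death day {day} < 0 for {rid!r}")
    new_records = []
    sched = dict(schedule)
    for rec in dataset.records:
        if rec.id in sched:
            day = sched[rec.id]
            new_records.append(
                IndividualRecord(
                    id=rec.id,
                    death_day=day,
                    censored=False,
                    clutches=[c for c in rec.clutches if c.day <= day],
                )
            )
        else:
            new_records.append(
                IndividualRecord(
                    id=rec.id,
                    death_day=rec.death_day,
                    censored=rec.censored,
                    clutches=list(rec.clutches),
                )
            )
    cohort, labels = _anonymize(new_records, label=dataset.cohort.label)
    return GroundTruthDataset(
        params=dataset.params,
        records=new_records,
        cohort=cohort,
        true_labels=labels,
        seed=dataset.seed,
    )


def misassignment_rate(dataset: GroundTruthDataset) -> float:
    """Fraction of clutches whose inferred round differs from the true one."""
    from .cohort_inference import assign_rounds

    assignment = assign_rounds(dataset.cohort)
    if not assignment.labels:
        return 0.0
    wrong = sum(
        1 for a, b in zip(assignment.labels, dataset.true_labels) if a != b
    )
    return wrong / len(assignment.labels)
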