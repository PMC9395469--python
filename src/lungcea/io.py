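"""Reading and writing parameter directories and result files.

A parameter directory holds one CSV per input family (all dialects are
plain comma-separated with ``#`` comment headers carrying provenance) plus
a ``manifest.yaml`` indexing them:

* ``scalars.csv`` — id,value for scalar parameters (onset curve,
  presentation, sensitivity, discount rates, ...);
* ``histology_mix.csv`` — histology,proportion;
* ``transitions.csv`` — long-format disease transitions
  (from_state,to_state,age_band,probability; unlisted pairs are zero, the
  diagonal is the row remainder);
* ``mortality.csv`` — age,probability (annual other-cause death);
* ``stage_distributions.csv`` — histology,stage,p_clinical,p_screened;
* ``costs.csv`` — category,histology,stage,amount_eur;
* ``utilities.csv`` — state,utility;
* ``uncertainty.csv`` — parameter_id,base,family,lo,hi;
* ``scenarios.csv`` — label,start_age,stop_age,interval;
* ``population.csv`` — group,start_age,count,smoking_prevalence.

Writing is deterministic: the same parameter set and seed produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .economics import CostTable, UtilityTable
from .params import MAX_AGE, ParameterSet
from .psa import UncertaintySpec
from .screening import LIFETIME, ScreeningScenario
from .states import build_state_space
from .transitions import disease_grid_from_long, disease_grid_to_long

PARAMETER_FILES = {
    "scalars": "scalars.csv",
    "histology_mix": "histology_mix.csv",
    "transitions": "transitions.csv",
    "mortality": "mortality.csv",
    "stage_distributions": "stage_distributions.csv",
    "costs": "costs.csv",
    "utilities": "utilities.csv",
    "uncertainty": "uncertainty.csv",
    "scenarios": "scenarios.csv",
    "population": "population.csv",
}
MANIFEST = "manifest.yaml"


@dataclass
class ParameterBundle:
    params: ParameterSet
    scenarios: list[ScreeningScenario]
    population: pd.DataFrame
    uncertainty: UncertaintySpec
    manifest: dict = field(default_factory=dict)


def _write_csv(path: Path, frame: pd.DataFrame, header_lines: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip", **kwargs)


def write_parameter_dir(path, params: ParameterSet, scenarios, population,
                        uncertainty: UncertaintySpec, seed: int | None = None) -> dict:
    """Write the full parameter directory; returns the manifest dict."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = ["lungcea parameter set"]
    if seed is not None:
        header.append(f"seed: {seed}")

    sp = params.space
    scalars = pd.DataFrame(
        [("onset.scale", params.onset_scale),
         ("onset.midpoint", params.onset_midpoint),
         ("onset.slope", params.onset_slope),
         ("onset.presentation", params.presentation_rate),
         ("screening.sensitivity", params.sensitivity),
         ("discount.cost", params.discount_cost),
         ("discount.effect", params.discount_qaly)],
        columns=["id", "value"],
    )
    _write_csv(path / PARAMETER_FILES["scalars"], scalars, header)
    _write_csv(path / PARAMETER_FILES["histology_mix"],
               pd.DataFrame({"histology": sp.histologies,
                             "proportion": params.histology_mix}), header)
    _write_csv(path / PARAMETER_FILES["transitions"], disease_grid_to_long(params), header)
    ages = np.arange(MAX_AGE + 1)
    _write_csv(path / PARAMETER_FILES["mortality"],
               pd.DataFrame({"age": ages,
                             "probability": params.other_cause_mortality}), header)
    rows = [(h, s, params.stage_dist_clinical[i, j], params.stage_dist_screened[i, j])
            for i, h in enumerate(sp.histologies) for j, s in enumerate(sp.stages)]
    _write_csv(path / PARAMETER_FILES["stage_distributions"],
               pd.DataFrame(rows, columns=["histology", "stage", "p_clinical", "p_screened"]),
               header)
    _write_csv(path / PARAMETER_FILES["costs"], params.cost_table().to_frame(), header)
    _write_csv(path / PARAMETER_FILES["utilities"], params.utility_table().to_frame(), header)
    _write_csv(path / PARAMETER_FILES["uncertainty"], uncertainty.to_frame(), header)
    _write_csv(path / PARAMETER_FILES["scenarios"],
               pd.DataFrame([(sc.label, sc.start_age, sc.stop_age, sc.interval)
                             for sc in scenarios],
                            columns=["label", "start_age", "stop_age", "interval"]),
               header)
    pop = population if isinstance(population, pd.DataFrame) else pd.DataFrame(population)
    _write_csv(path / PARAMETER_FILES["population"], pop, header)

    digest = hashlib.sha256()
    for name in sorted(PARAMETER_FILES.values()):
        digest.update((path / name).read_bytes())
    manifest = {
        "format": "lungcea-parameter-dir/1",
        "files": dict(PARAMETER_FILES),
        "seed": seed,
        "sha256": digest.hexdigest(),
    }
    with open(path / MANIFEST, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def read_parameter_dir(path) -> ParameterBundle:
    """Load a parameter directory back into model objects."""
    path = Path(path)
    manifest = {}
    if (path / MANIFEST).exists():
        with open(path / MANIFEST) as fh:
            manifest = yaml.safe_load(fh) or {}

    mix = _read_csv(path / PARAMETER_FILES["histology_mix"])
    dist = _read_csv(path / PARAMETER_FILES["stage_distributions"])
    histologies = tuple(mix["histology"])
    stages = tuple(dict.fromkeys(dist["stage"]))
    space = build_state_space(histology_labels=histologies, stage_labels=stages)
    H, S = space.n_histologies, space.n_stages

    scal_frame = _read_csv(path / PARAMETER_FILES["scalars"])
    scal = dict(zip(scal_frame["id"], scal_frame["value"].astype(float)))
    grid = disease_grid_from_long(_read_csv(path / PARAMETER_FILES["transitions"]), space)
    mort = _read_csv(path / PARAMETER_FILES["mortality"])
    mortality = np.zeros(int(mort["age"].max()) + 1)
    mortality[mort["age"].to_numpy()] = mort["probability"].to_numpy()

    clin = np.empty((H, S))
    scr = np.empty((H, S))
    for row in dist.itertuples(index=False):
        i, j = histologies.index(row.histology), stages.index(row.stage)
        clin[i, j] = row.p_clinical
        scr[i, j] = row.p_screened

    costs = CostTable.from_frame(_read_csv(path / PARAMETER_FILES["costs"]), space)
    utilities = UtilityTable.from_frame(_read_csv(path / PARAMETER_FILES["utilities"]), space)

    params = ParameterSet(
        space=space,
        histology_mix=mix["proportion"].to_numpy(dtype=float),
        onset_scale=scal["onset.scale"],
        onset_midpoint=scal["onset.midpoint"],
        onset_slope=scal["onset.slope"],
        presentation_rate=scal["onset.presentation"],
        sensitivity=scal["screening.sensitivity"],
        discount_cost=scal["discount.cost"],
        discount_qaly=scal["discount.effect"],
        other_cause_mortality=mortality,
        stage_dist_clinical=clin,
        stage_dist_screened=scr,
        cost_screening_round=costs.screening_round,
        cost_confirmation=costs.confirmation,
        cost_palliative=costs.palliative,
        cost_recurrence=costs.recurrence,
        cost_treatment=costs.treatment,
        cost_chronic=costs.chronic,
        utility_well=utilities.well,
        utility_post_treatment=utilities.post_treatment,
        utility_recurrence=utilities.recurrence,
        utility_stage=utilities.stage,
        **grid,
    )
    params.require_valid()

    scen_frame = _read_csv(path / PARAMETER_FILES["scenarios"],
                           dtype={"stop_age": str})
    scenarios = []
    for row in scen_frame.itertuples(index=False):
        stop = LIFETIME if row.stop_age == LIFETIME else int(row.stop_age)
        scenarios.append(ScreeningScenario(int(row.start_age), stop,
                                           int(row.interval), str(row.label)))
    population = _read_csv(path / PARAMETER_FILES["population"])
    uncertainty = UncertaintySpec.from_frame(_read_csv(path / PARAMETER_FILES["uncertainty"]))
    return ParameterBundle(params, scenarios, population, uncertainty, manifest)
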