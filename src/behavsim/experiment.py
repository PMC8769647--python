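"""Headless multi-subject experiment runner.

An experiment runs a cohort of subjects on the same task, each with its own
virtual setup, per-subject variable overrides, persistent variables (stored
at session end and restored on the next run) and summary variables (reported
per subject in a tab-separated table at the end of the run — the headless
stand-in for a clipboard copy).

Subjects execute sequentially in simulated time; because every session has
its own scheduler, board and seed, the per-subject data files are identical
whether subjects run together or alone.  Config files are YAML:

.. code-block:: yaml

    experiment: fc_training
    fixture: five-choice
    seed: 7
    params: {stage: S5}
    duration_ms: 1800000          # optional; fixture default otherwise
    subjects:
      m1: box1
      m2: box2
    subject_params:              # optional per-subject agent/stimulus spec
      m2: {p_correct: 0.9, p_incorrect: 0.05, p_premature: 0.05, p_omit: 0.0}
    variables:
      - {name: sd_ms, value: 2000, subject: all}
      - {name: n_trials, subject: all, summary: true}
      - {name: n_correct, subject: m1, value: 0, persistent: true}

A directive without ``value`` only tags the variable (summary/persistent).
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd
import yaml

from .session_log import archive_task_file
from .tasks import fixture_source, get_fixture, prepare_run


@dataclass
class VariableDirective:
    name: str
    value: object = None
    has_value: bool = False
    subject: str = "all"
    persistent: bool = False
    summary: bool = False


@dataclass
class ExperimentConfig:
    name: str
    fixture: str
    subjects: Dict[str, str]  # subject id -> setup id
    variables: List[VariableDirective] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    #: per-subject fixture parameter overrides (stimulus script / agent spec)
    subject_params: Dict[str, dict] = field(default_factory=dict)
    duration_ms: Optional[int] = None
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("subject ids must be unique")
        for subject in self.subject_params:
            if subject not in self.subjects:
                raise ValueError(f"subject_params for unknown subject {subject!r}")
        fixture = get_fixture(self.fixture)
        import_params = dict(fixture.default_params)
        import_params["duration_ms"] = self.duration_ms or fixture.default_duration_ms
        from .clock import Scheduler
        from .virtual_io import VirtualBoard

        defn = fixture.build(VirtualBoard(Scheduler()), import_params)
        declared = set(defn.variables)
        for d in self.variables:
            if d.name not in declared:
                raise ValueError(
                    f"variable directive names {d.name!r}, which task "
                    f"{defn.name!r} does not declare")
            if d.subject != "all" and d.subject not in self.subjects:
                raise ValueError(f"directive for unknown subject {d.subject!r}")


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration."""
    with open(str(path), encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    directives = []
    for item in raw.get("variables", []) or []:
        directives.append(VariableDirective(
            name=item["name"],
            value=item.get("value"),
            has_value="value" in item,
            subject=str(item.get("subject", "all")),
            persistent=bool(item.get("persistent", False)),
            summary=bool(item.get("summary", False)),
        ))
    config = ExperimentConfig(
        name=str(raw["experiment"]),
        fixture=str(raw["fixture"]),
        subjects={str(k): str(v) for k, v in (raw.get("subjects") or {}).items()},
        variables=directives,
        params=dict(raw.get("params") or {}),
        subject_params={str(k): dict(v) for k, v in
                        (raw.get("subject_params") or {}).items()},
        duration_ms=raw.get("duration_ms"),
        seed=int(raw.get("seed", 0)),
    )
    config.validate()
    return config


def save_config(config: ExperimentConfig, path) -> None:
    """Serialise a config back to YAML (round-trips through load_config)."""
    doc = {
        "experiment": config.name,
        "fixture": config.fixture,
        "seed": config.seed,
        "subjects": dict(config.subjects),
        "params": dict(config.params),
        "variables": [],
    }
    if config.subject_params:
        doc["subject_params"] = {k: dict(v) for k, v in config.subject_params.items()}
    if config.duration_ms is not None:
        doc["duration_ms"] = config.duration_ms
    for d in config.variables:
        item = {"name": d.name, "subject": d.subject,
                "persistent": d.persistent, "summary": d.summary}
        if d.has_value:
            item["value"] = d.value
        doc["variables"].append(item)
    with open(str(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


class PersistentStore:
    """Per-experiment persistent-variable storage, one human-readable JSON
    file mapping ``subject -> {variable: value}``.  Updated only at
    successful session end."""

    def __init__(self, path):
        self.path = str(path)
        self._data: Dict[str, dict] = {}
        if os.path.exists(self.path):
            with open(self.path, encoding="utf-8") as fh:
                self._data = json.load(fh)

    def get(self, subject: str, name: str, default=None):
        return self._data.get(subject, {}).get(name, default)

    def has(self, subject: str, name: str) -> bool:
        return name in self._data.get(subject, {})

    def set(self, subject: str, name: str, value) -> None:
        self._data.setdefault(subject, {})[name] = value

    def save(self) -> None:
        with open(self.path, "w", encoding="utf-8") as fh:
            json.dump(self._data, fh, indent=1, sort_keys=True)


def subject_seed(base_seed: int, subject: str) -> int:
    """Per-subject seed independent of cohort composition (below 2**31)."""
    return (base_seed * 1000003 + zlib.crc32(subject.encode("utf-8"))) % (2 ** 31)


@dataclass
class ExperimentResult:
    summary: pd.DataFrame
    summary_text: str
    session_paths: Dict[str, str]
    errored: List[str]
    store_path: Optional[str]


def summary_table(final_variables: Dict[str, dict], summary_names: List[str],
                  errored: List[str]) -> pd.DataFrame:
    """One row per subject, one column per summary variable, plus run status."""
    rows = []
    for subject in final_variables:
        row = {"subject": subject}
        for name in summary_names:
            row[name] = final_variables[subject].get(name)
        row["status"] = "errored" if subject in errored else "ok"
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject", *summary_names, "status"])


def run_experiment(config: ExperimentConfig, out_dir,
                   when: str = "1970-01-01T00:00:00") -> ExperimentResult:
    """Run every subject's session, write data files, persist variables, and
    assemble the summary table.

    One subject's errored run is marked in the table but does not abort the
    others.  Outputs under ``out_dir/<experiment>/``: per-subject session
    files ``<subject>-<when>.txt``, the archived task source, the persistent
    store ``persistent.json``, and ``summary.tsv``.
    """
    config.validate()
    exp_dir = os.path.join(str(out_dir), config.name)
    os.makedirs(exp_dir, exist_ok=True)
    stamp = when.replace(":", "").replace("T", "-")

    store = PersistentStore(os.path.join(exp_dir, "persistent.json"))
    summary_names = sorted({d.name for d in config.variables if d.summary})
    persistent_names = sorted({d.name for d in config.variables if d.persistent})

    session_paths: Dict[str, str] = {}
    final_vars: Dict[str, dict] = {}
    errored: List[str] = []
    archived = False

    for subject in config.subjects:
        path = os.path.join(exp_dir, f"{subject}-{stamp}.txt")
        overrides: Dict[str, object] = {}
        for d in config.variables:  # subject-specific directives win over "all"
            if d.has_value and d.subject == "all":
                overrides[d.name] = d.value
            if d.has_value and d.subject == subject:
                overrides[d.name] = d.value
        for name in persistent_names:
            if store.has(subject, name):
                overrides[name] = store.get(subject, name)

        subject_overrides = dict(config.params,
                                 **config.subject_params.get(subject, {}))
        if config.duration_ms:
            subject_overrides["duration_ms"] = config.duration_ms
        prepared = prepare_run(
            config.fixture,
            seed=subject_seed(config.seed, subject),
            params=subject_overrides,
            session_path=path,
            subject=subject,
            experiment=config.name,
            when=when,
            variables=overrides,
        )
        if not archived:
            archive_task_file(fixture_source(prepared.fixture),
                              prepared.engine.defn.name, exp_dir)
            archived = True
        summary = prepared.run()
        session_paths[subject] = path
        final_vars[subject] = summary["variables"]
        if summary["phase"] == "errored":
            errored.append(subject)
        else:
            for name in persistent_names:
                store.set(subject, name, summary["variables"][name])

    store.save()
    table = summary_table(final_vars, summary_names, errored)
    text = table.to_csv(sep="\t", index=False)
    with open(os.path.join(exp_dir, "summary.tsv"), "w", encoding="utf-8") as fh:
        fh.write(text)
    return ExperimentResult(summary=table, summary_text=text,
                            session_paths=session_paths, errored=errored,
                            store_path=store.path)
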