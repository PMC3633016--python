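"""Benchmark-suite driver: Cartesian pattern x target x variant runs.

A suite config (YAML) lists pattern files, target files, variants and
modes; every combination is executed with a per-run timeout and written
as one CSV row, followed by an aggregate block with mean/SD per
(variant, mode) group.  Timed-out runs keep their row but are excluded
from the aggregate means; a group whose runs all timed out reports empty
means rather than zeros.
"""

from __future__ import annotations

import csv
import logging
import statistics
import time
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Union

import yaml

from .domains import compute_domains
from .graph import LabeledGraph, read_graph
from .matching import DEFAULT_TIMEOUT, MatchMode, count_matches

log = logging.getLogger(__name__)

CSV_COLUMNS = ["pattern", "target", "variant", "mode", "visited", "matches", "seconds", "timed_out"]


@dataclass
class RunRecord:
    """One pattern-vs-target execution and its search statistics."""

    pattern: str
    target: str
    variant: str  # "ri" | "ri-ds"
    mode: str  # "monomorphism" | "induced"
    visited: int
    matches: int
    seconds: float
    timed_out: bool

    def as_row(self) -> list:
        return [
            self.pattern,
            self.target,
            self.variant,
            self.mode,
            self.visited,
            self.matches,
            f"{self.seconds:.6f}",
            int(self.timed_out),
        ]


@dataclass
class SuiteConfig:
    patterns: list[str]
    targets: list[str]
    variants: list[str]
    modes: list[str]
    dialect: str = "directed"
    timeout: float = DEFAULT_TIMEOUT

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SuiteConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(
            patterns=list(raw["patterns"]),
            targets=list(raw["targets"]),
            variants=list(raw.get("variants", ["ri"])),
            modes=list(raw.get("modes", ["monomorphism"])),
            dialect=raw.get("dialect", "directed"),
            timeout=float(raw.get("timeout", DEFAULT_TIMEOUT)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for v in self.variants:
            if v not in ("ri", "ri-ds"):
                raise ValueError(f"unknown variant {v!r}")
        for m in self.modes:
            if m not in ("monomorphism", "induced"):
                raise ValueError(f"unknown mode {m!r}")
        missing = [f for f in self.patterns + self.targets if not Path(f).exists()]
        if missing:
            raise FileNotFoundError(f"missing graph files: {missing}")


def run_one(
    pattern: LabeledGraph,
    target: LabeledGraph,
    variant: str,
    mode: str,
    timeout: Optional[float],
) -> RunRecord:
    """Execute a single run.

    The reported ``seconds`` is the matching time: search only for the
    plain variant, search plus domain preprocessing for ``ri-ds`` (the
    preprocessing is part of that variant's matching process).
    """
    t0 = time.monotonic()
    domains = compute_domains(pattern, target) if variant == "ri-ds" else None
    n, stats = count_matches(
        pattern, target, MatchMode(kind=mode), domains=domains, timeout=timeout
    )
    seconds = time.monotonic() - t0
    return RunRecord(
        pattern=pattern.name,
        target=target.name,
        variant=variant,
        mode=mode,
        visited=stats.visited_nodes,
        matches=n,
        seconds=seconds,
        timed_out=stats.timed_out,
    )


def run_suite(config: SuiteConfig, out: Union[str, IO[str]]) -> list[RunRecord]:
    """Run the full Cartesian product and write the CSV report."""
    config.validate()
    patterns = [read_graph(p, config.dialect) for p in config.patterns]
    targets = [read_graph(t, config.dialect) for t in config.targets]
    records: list[RunRecord] = []
    for pat in patterns:
        for tgt in targets:
            for variant in config.variants:
                for mode in config.modes:
                    rec = run_one(pat, tgt, variant, mode, config.timeout)
                    log.info(
                        "%s vs %s [%s/%s]: %d matches, %d visited, %.3fs%s",
                        rec.pattern, rec.target, variant, mode,
                        rec.matches, rec.visited, rec.seconds,
                        " (TIMEOUT)" if rec.timed_out else "",
                    )
                    records.append(rec)
    if isinstance(out, (str, Path)):
        with open(out, "w", newline="", encoding="utf-8") as fh:
            _write_csv(records, fh)
    else:
        _write_csv(records, out)
    return records


def _write_csv(records: list[RunRecord], fh: IO[str]) -> None:
    w = csv.writer(fh)
    w.writerow(CSV_COLUMNS)
    for rec in records:
        w.writerow(rec.as_row())
    w.writerow([])
    w.writerow(["# aggregate", "group", "", "", "mean_visited/sd", "mean_matches/sd", "mean_seconds/sd", "n_completed"])
    groups: dict[tuple[str, str], list[RunRecord]] = {}
    for rec in records:
        groups.setdefault((rec.variant, rec.mode), []).append(rec)
    for (variant, mode), recs in sorted(groups.items()):
        done = [r for r in recs if not r.timed_out]

        def mean_sd(values: list[float]) -> str:
            if not values:
                return ""  # all runs timed out: empty, not zero
            mean = statistics.fmean(values)
            sd = statistics.stdev(values) if len(values) > 1 else 0.0
            return f"{mean:.4f}/{sd:.4f}"

        w.writerow(
            [
                "aggregate",
                f"{variant}:{mode}",
                "",
                "",
                mean_sd([r.visited for r in done]),
                mean_sd([r.matches for r in done]),
                mean_sd([r.seconds for r in done]),
                len(done),
            ]
        )
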