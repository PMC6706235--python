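"""Treatment grid, replicate management, seeding, and configuration parsing.

The study design crosses two cell-death modes (direct benefit to kin,
indirect benefit via harm to nonkin) with kin-inclusivity levels
{0, 1, 3, 5, 30, 100} and, for every treatment, a no-effect control that is
identical except that the effect factor is the identity 1. The full-scale
profile runs 60,000 updates x 30 replicates on a 60x60 grid; the bundled
``reduced`` profile (30x30, 3,000 updates, 10 replicates) makes the same
qualitative comparisons tractable on a desktop.

Replicate ``r`` of a treatment always uses seed ``base_seed + r``, and every
output directory carries a bit-exact echo of the resolved configuration plus
the seeds used, so any run can be reproduced byte-identically.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, UsageError
from .metrics import (EndpointSummary, endpoint_from_timeseries,
                      mean_affected_per_event, mean_cheater_kin_per_event)
from .world import SimulationConfig, World

#: Bundled scale profiles. "full" is the headline study scale; "reduced" is
#: the desk-scale preset used by the test suite.
PROFILES = {
    "full": {"grid_width": 60, "grid_height": 60, "updates": 60_000,
             "replicates": 30},
    "reduced": {"grid_width": 30, "grid_height": 30, "updates": 3_000,
                "replicates": 10},
}

#: Kin-inclusivity levels of the study sweep.
KIL_SWEEP = (0, 1, 3, 5, 30, 100)

_SPEC_FIELDS = {"name", "mode", "effect_factor", "kil", "updates",
                "replicates", "base_seed"}
_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclass(frozen=True)
class TreatmentSpec:
    """One experimental condition (a point of the treatment grid)."""

    name: str
    mode: str = "direct"
    effect_factor: float = 5.0
    kil: int = 3
    updates: int = 60_000
    replicates: int = 30
    base_seed: int = 42

    def seed_for(self, replicate: int) -> int:
        """Replicate ``r`` uses seed ``base_seed + r`` (documented policy)."""
        return self.base_seed + replicate

    def control(self) -> "TreatmentSpec":
        """The paired no-effect control: identical except effect_factor = 1."""
        return dataclasses.replace(self, name=f"{self.name}-control",
                                   effect_factor=1.0)

    def resolve_config(self, base: SimulationConfig | None = None,
                       replicate: int = 0) -> SimulationConfig:
        base = base if base is not None else SimulationConfig()
        return base.with_(mode=self.mode, effect_factor=self.effect_factor,
                          kil=self.kil, updates=self.updates,
                          seed=self.seed_for(replicate))


def paper_grid(profile: str = "full", base_seed: int = 42,
               kils: Sequence[int] = KIL_SWEEP) -> list[TreatmentSpec]:
    """The full 2 modes x |kils| KILs x {treatment, control} grid (24 specs).

    Each spec gets its own seed block (``base_seed + 1000*i``) so replicate
    streams never collide across conditions.
    """
    prof = _profile(profile)
    specs: list[TreatmentSpec] = []
    i = 0
    for mode in ("direct", "indirect"):
        for kil in kils:
            t = TreatmentSpec(name=f"{mode}-pcd-{kil}", mode=mode,
                              effect_factor=5.0, kil=kil,
                              updates=prof["updates"],
                              replicates=prof["replicates"],
                              base_seed=base_seed + 1000 * i)
            specs.append(t)
            i += 1
            specs.append(dataclasses.replace(
                t.control(), base_seed=base_seed + 1000 * i))
            i += 1
    return specs


def _profile(name: str) -> dict:
    if name not in PROFILES:
        raise ConfigurationError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}")
    return PROFILES[name]


def base_config_for_profile(profile: str = "full", **overrides) -> SimulationConfig:
    prof = {k: v for k, v in _profile(profile).items() if k in _CONFIG_FIELDS}
    prof.update(overrides)
    return SimulationConfig(**prof)


# ---------------------------------------------------------------------------
# run orchestration
# ---------------------------------------------------------------------------

def _write_provenance(rep_dir: Path, cfg: SimulationConfig,
                      spec: TreatmentSpec, replicate: int) -> None:
    doc = {"treatment": dataclasses.asdict(spec),
           "replicate": replicate,
           "config": dataclasses.asdict(cfg)}
    (rep_dir / "config.yaml").write_text(yaml.safe_dump(doc, sort_keys=True))


_TS_COLUMNS = ["update", "population", "pct_attempting_pcd", "carrier_pct",
               "mean_merit", "n_pcd_events", "pcd_incidence_pct", "extinct"]


def run_replicate(spec: TreatmentSpec, replicate_index: int,
                  base_config: SimulationConfig | None = None,
                  out_dir: str | Path | None = None) -> EndpointSummary:
    """Run one seeded replicate of a treatment and summarize its endpoint.

    If ``out_dir`` is given, writes ``<out>/<name>/rep<k>/`` containing
    ``timeseries.csv`` (appended incrementally every sampling interval),
    ``events.csv``, ``dump.tsv`` (final population), and a ``config.yaml``
    provenance echo. Extinction flags the endpoint; partial outputs are kept.
    """
    cfg = spec.resolve_config(base_config, replicate_index)
    world = World(cfg)
    world.inject_ancestor()

    writer = handle = None
    rep_dir = None
    if out_dir is not None:
        rep_dir = Path(out_dir) / spec.name / f"rep{replicate_index:03d}"
        rep_dir.mkdir(parents=True, exist_ok=True)
        _write_provenance(rep_dir, cfg, spec, replicate_index)
        handle = open(rep_dir / "timeseries.csv", "w", newline="")
        writer = csv.DictWriter(handle, fieldnames=_TS_COLUMNS)
        writer.writeheader()

    def on_sample(row: dict) -> None:
        if writer is not None:
            writer.writerow({k: row[k] for k in _TS_COLUMNS})
            handle.flush()

    try:
        world.run(on_sample=on_sample)
    finally:
        if handle is not None:
            handle.close()

    if rep_dir is not None:
        world.events_df().to_csv(rep_dir / "events.csv", index=False)
        world.dump_df().to_csv(rep_dir / "dump.tsv", sep="\t", index=False)

    ep = endpoint_from_timeseries(world.timeseries_df(), cfg.endpoint_window)
    return EndpointSummary(
        treatment=spec.name,
        replicate=replicate_index,
        seed=cfg.seed,
        pct_attempting_pcd=ep["pct_attempting_pcd"],
        carrier_pct=ep["carrier_pct"],
        n_events=len(world.events),
        mean_kin_affected=mean_affected_per_event(world.events, side="kin"),
        mean_nonkin_affected=mean_affected_per_event(world.events, side="nonkin"),
        mean_cheater_kin=mean_cheater_kin_per_event(world.events),
        extinct=world.extinct,
    )


def run_grid(specs: Sequence[TreatmentSpec],
             base_config: SimulationConfig | None = None,
             out_dir: str | Path | None = None,
             progress: bool = False) -> pd.DataFrame:
    """Run all replicates of all specs; one endpoint row per (name, replicate).

    Order is deterministic (specs in list order, replicates ascending) and a
    seed ledger is written next to the outputs, so a rerun from the same
    specs reproduces the table exactly.
    """
    if not specs:
        raise UsageError("run_grid requires a non-empty spec list")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise UsageError(f"duplicate spec names: {dupes}")
    ledger = []
    rows = []
    for spec in specs:
        for r in range(spec.replicates):
            if progress:
                print(f"[unicell] {spec.name} replicate {r} "
                      f"(seed {spec.seed_for(r)})", flush=True)
            summary = run_replicate(spec, r, base_config, out_dir)
            rows.append(dataclasses.asdict(summary))
            ledger.append(f"{spec.name}\t{r}\t{spec.seed_for(r)}")
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "seeds.txt").write_text("\n".join(ledger) + "\n")
        table.to_csv(out / "endpoints.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# configuration parsing
# ---------------------------------------------------------------------------

def parse_config(path: str | Path | None = None,
                 overrides: dict | None = None
                 ) -> tuple[SimulationConfig, list[TreatmentSpec]]:
    """Resolve a flat key/value config document plus overrides.

    Recognized keys are the :class:`SimulationConfig` fields, the
    :class:`TreatmentSpec` fields, ``profile``, and ``treatments`` (a list of
    per-treatment mappings). Every default stated by the model applies; an
    unknown or out-of-range key raises a :class:`ConfigurationError` naming
    it. Returns the resolved base config and the treatment list (a single
    spec named ``run`` when no ``treatments`` block is given).
    """
    doc: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must be a mapping")
        doc.update(loaded)
    if overrides:
        doc.update({k: v for k, v in overrides.items() if v is not None})

    known = _CONFIG_FIELDS | _SPEC_FIELDS | {"profile", "treatments"}
    for key in doc:
        if key not in known:
            raise ConfigurationError(f"unknown configuration key: {key!r}")

    cfg_kwargs: dict = {}
    if "profile" in doc:
        cfg_kwargs.update({k: v for k, v in _profile(doc["profile"]).items()
                           if k in _CONFIG_FIELDS})
    cfg_kwargs.update({k: doc[k] for k in doc if k in _CONFIG_FIELDS})
    try:
        base = SimulationConfig(**cfg_kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(str(exc)) from exc

    spec_defaults = {
        "mode": base.mode, "effect_factor": base.effect_factor,
        "kil": base.kil, "updates": base.updates,
    }
    if "profile" in doc:
        spec_defaults["replicates"] = _profile(doc["profile"])["replicates"]
    spec_defaults.update({k: doc[k] for k in doc if k in _SPEC_FIELDS})

    specs: list[TreatmentSpec] = []
    if "treatments" in doc:
        if not isinstance(doc["treatments"], list) or not doc["treatments"]:
            raise ConfigurationError("'treatments' must be a non-empty list")
        for i, entry in enumerate(doc["treatments"]):
            if not isinstance(entry, dict):
                raise ConfigurationError(f"treatments[{i}] must be a mapping")
            for key in entry:
                if key not in _SPEC_FIELDS:
                    raise ConfigurationError(
                        f"unknown treatment key in treatments[{i}]: {key!r}")
            kwargs = dict(spec_defaults)
            kwargs.update(entry)
            kwargs.setdefault("name", f"treatment-{i}")
            specs.append(TreatmentSpec(**kwargs))
    else:
        kwargs = dict(spec_defaults)
        kwargs.setdefault("name", "run")
        specs.append(TreatmentSpec(**kwargs))

    # cross-validate each spec against the base config (e.g. kil <= L)
    for spec in specs:
        spec.resolve_config(base)
    return base, specs
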