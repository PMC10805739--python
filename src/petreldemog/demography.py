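"""Demographic models for the structured coalescent.

A :class:`DemographicModel` describes one or two demes backward in time:
present-day diploid sizes plus a time-ordered list of events (instantaneous
resizes, backward-time joins representing forward-time splits, and changes to
piecewise-constant asymmetric migration).  Models are validated on
construction and compiled to flat numpy arrays for the simulation kernels.

Conventions
-----------
* Time is measured in generations before present (continuous, >= 0).
  Conversion to years (multiplying by the generation time) happens only at
  reporting.
* Sizes are diploid individuals; a deme of size N holds 2N haploid lineages.
* Migration is parameterized as ``(2Nm)_{s->r}``: the expected number of
  haploid immigrants entering recipient deme ``r`` per generation whose
  source (forward in time) is deme ``s``.  Backward in time a lineage
  currently in ``r`` jumps to ``s`` at rate ``(2Nm)_{s->r} / (2 N_r)`` per
  generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import yaml

__all__ = [
    "Resize",
    "Join",
    "SetMigration",
    "DemographicModel",
    "SampleConfig",
    "ModelValidationError",
    "build_model",
]

TIME_CEILING = 1e9  # generations; hard error for non-coalescing configurations


class ModelValidationError(ValueError):
    """Raised when a demographic model specification is inconsistent."""


@dataclass(frozen=True)
class Resize:
    """At ``time``, deme ``deme`` instantaneously takes diploid size ``size``
    (looking further into the past)."""

    time: float
    deme: str
    size: float


@dataclass(frozen=True)
class Join:
    """At ``time``, all lineages of ``source`` move into ``dest`` (backward
    merge = forward-time split of ``dest`` into ``dest`` + ``source``)."""

    time: float
    source: str
    dest: str


@dataclass(frozen=True)
class SetMigration:
    """From ``time`` onward (into the past) the forward-time flow from
    ``source`` into ``dest`` is ``rate_2nm`` haploid immigrants/generation."""

    time: float
    source: str
    dest: str
    rate_2nm: float


Event = Resize | Join | SetMigration


@dataclass
class CompiledModel:
    """Flat-array view of a model, consumed by the numba kernels."""

    n_demes: int
    start_sizes: np.ndarray  # (n_demes,) diploid sizes at t=0
    start_mig: np.ndarray  # (n_demes, n_demes) 2Nm[s, r]
    ev_time: np.ndarray  # (n_ev,) float64, non-decreasing
    ev_kind: np.ndarray  # (n_ev,) int64: 0 resize, 1 join, 2 set_migration
    ev_a: np.ndarray  # resize: deme; join/set_migration: source index
    ev_b: np.ndarray  # join/set_migration: dest index (resize: -1)
    ev_val: np.ndarray  # resize: new size; set_migration: 2Nm; join: 0


@dataclass
class DemographicModel:
    """Validated two-deme (or single-deme) history.

    Parameters
    ----------
    demes
        Ordered deme names.
    sizes
        Present-day diploid sizes, aligned with ``demes``.
    events
        Time-ordered events (ties allowed; applied in list order).
    migration
        Initial (present-day) ``{(source, dest): 2Nm}`` entries; forward-time
        direction, absent pairs default to 0.
    label
        Free-text identifier.
    """

    demes: list[str]
    sizes: list[float]
    events: list[Event] = field(default_factory=list)
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def deme_index(self, name: str) -> int:
        try:
            return self.demes.index(name)
        except ValueError:
            raise ModelValidationError(f"unknown deme {name!r}") from None

    def validate(self) -> None:
        if len(self.demes) != len(set(self.demes)):
            raise ModelValidationError("duplicate deme names")
        if len(self.sizes) != len(self.demes):
            raise ModelValidationError("sizes must align with demes")
        for name, size in zip(self.demes, self.sizes):
            if not size > 0:
                raise ModelValidationError(f"deme {name!r} has non-positive size {size}")
        for (src, dst), rate in self.migration.items():
            self.deme_index(src), self.deme_index(dst)
            if src == dst:
                raise ModelValidationError(f"self-migration {src!r}->{dst!r}")
            if rate < 0:
                raise ModelValidationError(f"negative migration rate for {src}->{dst}")

        times = [ev.time for ev in self.events]
        if any(t < 0 for t in times):
            raise ModelValidationError("event times must be >= 0")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ModelValidationError("events must be in non-decreasing time order")

        alive = set(self.demes)
        mig_active = {k: v for k, v in self.migration.items() if v > 0}
        for ev in self.events:
            if isinstance(ev, Resize):
                self.deme_index(ev.deme)
                if ev.deme not in alive:
                    raise ModelValidationError(
                        f"resize of deme {ev.deme!r} at t={ev.time} after it was joined away"
                    )
                if not ev.size > 0:
                    raise ModelValidationError(
                        f"resize of {ev.deme!r} at t={ev.time} to non-positive size {ev.size}"
                    )
            elif isinstance(ev, Join):
                self.deme_index(ev.source), self.deme_index(ev.dest)
                if ev.source == ev.dest:
                    raise ModelValidationError(f"join of {ev.source!r} onto itself")
                for name in (ev.source, ev.dest):
                    if name not in alive:
                        raise ModelValidationError(
                            f"join involving deme {name!r} at t={ev.time} after it was joined away"
                        )
                alive.discard(ev.source)
                mig_active = {
                    k: v for k, v in mig_active.items() if ev.source not in k
                }
            elif isinstance(ev, SetMigration):
                self.deme_index(ev.source), self.deme_index(ev.dest)
                if ev.source == ev.dest:
                    raise ModelValidationError("self-migration event")
                if ev.rate_2nm < 0:
                    raise ModelValidationError(
                        f"negative migration rate at t={ev.time} for {ev.source}->{ev.dest}"
                    )
                for name in (ev.source, ev.dest):
                    if name not in alive:
                        raise ModelValidationError(
                            f"migration set toward/from joined-away deme {name!r} at t={ev.time}"
                        )
                if ev.rate_2nm > 0:
                    mig_active[(ev.source, ev.dest)] = ev.rate_2nm
                else:
                    mig_active.pop((ev.source, ev.dest), None)
            else:  # pragma: no cover - exhaustiveness guard
                raise ModelValidationError(f"unknown event {ev!r}")

        if len(alive) > 1 and not mig_active:
            # Lineages stranded in disconnected demes can never coalesce.
            raise ModelValidationError(
                "model ends with several demes and no migration: lineages cannot coalesce"
            )

    # ------------------------------------------------------------------
    def compile(self) -> CompiledModel:
        nd = len(self.demes)
        start_sizes = np.asarray(self.sizes, dtype=np.float64)
        start_mig = np.zeros((nd, nd))
        for (src, dst), rate in self.migration.items():
            start_mig[self.deme_index(src), self.deme_index(dst)] = rate
        n_ev = len(self.events)
        ev_time = np.empty(n_ev)
        ev_kind = np.empty(n_ev, dtype=np.int64)
        ev_a = np.empty(n_ev, dtype=np.int64)
        ev_b = np.full(n_ev, -1, dtype=np.int64)
        ev_val = np.zeros(n_ev)
        for i, ev in enumerate(self.events):
            ev_time[i] = ev.time
            if isinstance(ev, Resize):
                ev_kind[i] = 0
                ev_a[i] = self.deme_index(ev.deme)
                ev_val[i] = ev.size
            elif isinstance(ev, Join):
                ev_kind[i] = 1
                ev_a[i] = self.deme_index(ev.source)
                ev_b[i] = self.deme_index(ev.dest)
            else:
                ev_kind[i] = 2
                ev_a[i] = self.deme_index(ev.source)
                ev_b[i] = self.deme_index(ev.dest)
                ev_val[i] = ev.rate_2nm
        return CompiledModel(nd, start_sizes, start_mig, ev_time, ev_kind, ev_a, ev_b, ev_val)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        evs = []
        for ev in self.events:
            if isinstance(ev, Resize):
                evs.append({"kind": "resize", "time": ev.time, "deme": ev.deme, "size": ev.size})
            elif isinstance(ev, Join):
                evs.append({"kind": "join", "time": ev.time, "source": ev.source, "dest": ev.dest})
            else:
                evs.append(
                    {
                        "kind": "set_migration",
                        "time": ev.time,
                        "source": ev.source,
                        "dest": ev.dest,
                        "rate_2nm": ev.rate_2nm,
                    }
                )
        return {
            "label": self.label,
            "demes": [
                {"name": n, "size": s} for n, s in zip(self.demes, self.sizes)
            ],
            "migration": [
                {"source": s, "dest": d, "rate_2nm": r}
                for (s, d), r in sorted(self.migration.items())
            ],
            "events": evs,
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "DemographicModel":
        return build_model(spec)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        with open(path) as fh:
            return build_model(yaml.safe_load(fh))


def build_model(spec: dict) -> DemographicModel:
    """Build and validate a :class:`DemographicModel` from a structured spec.

    ``spec`` mirrors :meth:`DemographicModel.to_dict`; the round-trip is
    lossless.
    """

    try:
        demes = [d["name"] for d in spec["demes"]]
        sizes = [float(d["size"]) for d in spec["demes"]]
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(f"malformed deme list: {exc}") from exc
    migration = {
        (m["source"], m["dest"]): float(m["rate_2nm"])
        for m in spec.get("migration", [])
    }
    events: list[Event] = []
    for ev in spec.get("events", []):
        kind = ev.get("kind")
        if kind == "resize":
            events.append(Resize(float(ev["time"]), ev["deme"], float(ev["size"])))
        elif kind == "join":
            events.append(Join(float(ev["time"]), ev["source"], ev["dest"]))
        elif kind == "set_migration":
            events.append(
                SetMigration(float(ev["time"]), ev["source"], ev["dest"], float(ev["rate_2nm"]))
            )
        else:
            raise ModelValidationError(f"unknown event kind {kind!r}")
    return DemographicModel(
        demes=demes,
        sizes=sizes,
        events=events,
        migration=migration,
        label=spec.get("label", ""),
    )


@dataclass
class SampleConfig:
    """Sampling design: per-deme haploid sample sizes plus mutation scaling.

    ``sequence_length`` (sites) and ``mu`` (substitutions/site/generation)
    matter only for absolute-mode mutation placement and for anchoring
    absolute parameter scales; conditioned-segregating SNP simulation depends
    on neither.
    """

    haploid_sizes: dict[str, int]
    sequence_length: float = 1.0
    mu: float = 2.89e-9

    def __post_init__(self) -> None:
        total = sum(self.haploid_sizes.values())
        if total < 2:
            raise ModelValidationError("need at least 2 haploid samples overall")
        if any(n < 0 for n in self.haploid_sizes.values()):
            raise ModelValidationError("negative sample size")
        if not self.sequence_length > 0:
            raise ModelValidationError("sequence_length must be > 0")
        if not self.mu > 0:
            raise ModelValidationError("mu must be > 0")

    def sizes_for(self, model: DemographicModel) -> np.ndarray:
        out = np.zeros(len(model.demes), dtype=np.int64)
        for name, n in self.haploid_sizes.items():
            out[model.deme_index(name)] = n
        return out
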