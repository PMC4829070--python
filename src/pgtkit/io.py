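"""Configuration, file formats and reports.

Plain-text formats only: phantom spec files (one ``material thickness_mm``
per line), spectrum TSV with a metadata header, Compton event TSV, YAML run
configs validated against a strict schema, and JSON-lines reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .model import BeamSpec, DetectorSpec, PGTSpectrum
from .transport import MATERIALS, LayeredPhantom, Material, Slice

__all__ = [
    "RunConfig",
    "load_config",
    "read_phantom",
    "write_phantom",
    "read_spectrum",
    "write_spectrum",
    "read_events",
    "write_events",
    "write_report",
    "stage_seed",
]


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    energy: float = Field(gt=0, description="initial proton energy, MeV")
    phantom: str = Field(description="phantom spec path or preset name")
    f_bunch: float = Field(default=106.0, gt=0)
    sigma_bunch: float | None = Field(default=None, ge=0)
    n_protons: float = Field(default=1e8, gt=0)
    gamma_yield: float = Field(default=0.16, ge=0)
    alpha: float = 90.0
    distance: float = Field(default=300.0, gt=0)
    radius: float = Field(default=25.4, gt=0)
    z_ref: float | None = None
    efficiency: float = Field(default=1.0, gt=0, le=1)
    sigma_det: float = Field(default=0.3, ge=0)
    binning: int = Field(default=100, ge=2)
    background: float = Field(default=0.05, ge=0, lt=1)
    seed: int = 0
    output: str | None = None

    def beam(self) -> BeamSpec:
        return BeamSpec(self.energy, self.f_bunch, self.sigma_bunch,
                        self.n_protons, self.gamma_yield)

    def detector(self) -> DetectorSpec:
        return DetectorSpec(self.alpha, self.distance, self.radius,
                            self.efficiency, self.sigma_det, self.z_ref)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def stage_seed(seed: int, stage: int) -> np.random.SeedSequence:
    """Derive a per-stage seed from one global seed.

    Stages are numbered; adding a stage never perturbs the streams of
    earlier stages because each stage keys an independent SeedSequence.
    """
    return np.random.SeedSequence(entropy=seed, spawn_key=(stage,))


# ---------------------------------------------------------------------------
# phantom spec files


def read_phantom(path: str | Path, registry: dict[str, Material] | None = None) -> LayeredPhantom:
    """Parse a phantom spec file: one ``material thickness_mm`` per line,
    ``#`` starts a comment.  Materials resolve against ``registry``
    (default: the built-in registry)."""
    registry = registry if registry is not None else MATERIALS
    slices = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            name, thickness = line.split()
        except ValueError:
            raise ValueError(f"{path}:{lineno}: expected 'material thickness_mm'") from None
        if name not in registry:
            raise KeyError(f"{path}:{lineno}: unknown material {name!r}; "
                           f"known: {sorted(registry)}")
        slices.append(Slice(registry[name], float(thickness)))
    if not slices:
        raise ValueError(f"{path}: no slices found")
    return LayeredPhantom(slices)


def write_phantom(phantom: LayeredPhantom, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# material thickness_mm\n")
        for s in phantom.slices:
            fh.write(f"{s.material.name} {s.thickness:.6g}\n")


# ---------------------------------------------------------------------------
# spectrum TSV


def write_spectrum(spectrum: PGTSpectrum, path: str | Path) -> None:
    """Write a spectrum as TSV with a metadata header line."""
    meta = spectrum.meta
    with open(path, "w") as fh:
        fh.write(f"# n_protons={meta.get('n_protons', 'nan')} "
                 f"seed={meta.get('seed', 'none')} "
                 f"t_bunch_ns={float(meta.get('t_bunch_ns', spectrum.bin_edges[-1])):.17g}\n")
        fh.write("# bin_left_ns\tcounts\n")
        for left, c in zip(spectrum.bin_edges[:-1], spectrum.counts):
            fh.write(f"{float(left):.17g}\t{float(c):.17g}\n")
        fh.write(f"{float(spectrum.bin_edges[-1]):.17g}\t-\n")  # final edge sentinel


def read_spectrum(path: str | Path) -> PGTSpectrum:
    meta: dict = {}
    edges, counts = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for tok in line.lstrip("# ").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if v == "none":
                        meta[k] = None
                    else:
                        try:
                            meta[k] = float(v)
                        except ValueError:
                            meta[k] = v
            continue
        if not line.strip():
            continue
        left, c = line.split("\t")
        edges.append(float(left))
        if c != "-":
            counts.append(float(c))
    return PGTSpectrum(np.array(edges), np.array(counts), meta)


# ---------------------------------------------------------------------------
# Compton event TSV


def write_events(events, path: str | Path) -> None:
    """Write Compton events as TSV: xs ys zs xa ya za Ls La."""
    with open(path, "w") as fh:
        fh.write("# xs\tys\tzs\txa\tya\tza\tLs\tLa\n")
        for ev in events:
            fh.write("\t".join(f"{float(v):.17g}" for v in (*ev.r_s, *ev.r_a, ev.L_s, ev.L_a)))
            fh.write("\n")


def read_events(path: str | Path):
    from .detector import ComptonEvent

    out = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        vals = [float(v) for v in line.split("\t")]
        out.append(ComptonEvent(tuple(vals[0:3]), tuple(vals[3:6]), vals[6], vals[7]))
    return out


# ---------------------------------------------------------------------------
# reports


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(results, path: str | Path, fmt: str = "jsonl", seed: int | None = None) -> None:
    """Serialize a list of result objects.

    ``jsonl`` writes one JSON object per result with a leading provenance
    line; ``tsv`` writes dataclass fields as columns.  Raises on empty
    input.
    """
    results = list(results)
    if not results:
        raise ValueError("refusing to write an empty report")
    if fmt == "jsonl":
        with open(path, "w") as fh:
            fh.write(json.dumps({"tool": "pgtkit", "version": __version__, "seed": seed}) + "\n")
            for r in results:
                fh.write(json.dumps(_to_jsonable(r)) + "\n")
    elif fmt == "tsv":
        first = results[0]
        if dataclasses.is_dataclass(first):
            names = [f.name for f in dataclasses.fields(first)]
            with open(path, "w") as fh:
                fh.write(f"# pgtkit {__version__} seed={seed}\n")
                fh.write("\t".join(names) + "\n")
                for r in results:
                    fh.write("\t".join(str(_to_jsonable(getattr(r, n))) for n in names) + "\n")
        else:
            with open(path, "w") as fh:
                fh.write(f"# pgtkit {__version__} seed={seed}\n")
                for r in results:
                    fh.write("\t".join(str(v) for v in np.atleast_1d(r)) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
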