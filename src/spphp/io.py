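"""File formats, configuration, and run manifests.

Spectra travel as two-column delimited text (wavenumber in cm^-1 plus
value; one mandatory header line) or JCAMP-DX; datasets as a directory
of delimited tables plus a YAML metadata file; run configuration as a
strict YAML mapping. Wavenumber grids are canonically ascending --
descending input files are re-sorted with a logged warning, never
silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .polariton import (
    CoupledSystem,
    DielectricModel,
    LorentzOscillator,
    PolaritonMode,
)
from .spectra import ABSORBANCE_MOD, REFLECTANCE, DifferentialSpectrum, Spectrum
from .synth import (
    SPECIES,
    KineticsParams,
    ReactantSignature,
    SyntheticDataset,
    VibrationalBand,
)

logger = logging.getLogger("spphp")

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_jcamp",
    "save_dataset",
    "load_dataset",
    "RunConfig",
    "load_config",
    "manifest",
]

_KIND_ALIASES = {
    "reflectance": REFLECTANCE,
    "absorbance_mOD": ABSORBANCE_MOD,
    "absorbance": ABSORBANCE_MOD,
}


def write_spectrum(s: Spectrum | DifferentialSpectrum, path) -> None:
    """Write a spectrum as two-column tab-delimited text with a header
    naming the units, full-precision scientific notation."""
    path = Path(path)
    if isinstance(s, Spectrum):
        kind, values = s.kind, s.values
    else:
        kind, values = ABSORBANCE_MOD, s.absorbance
    with path.open("w") as fh:
        fh.write(f"wavenumber_cm-1\t{kind}\n")
        for w, v in zip(s.wavenumbers, values):
            fh.write(f"{w:.17e}\t{v:.17e}\n")


def read_spectrum(path, fmt: str = "delimited") -> Spectrum:
    """Read a spectrum from delimited text or JCAMP-DX.

    The grid is forced ascending (with a warning when the file was
    descending); duplicate or non-numeric rows raise.
    """
    if fmt == "jcamp":
        return read_jcamp(path)
    if fmt != "delimited":
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if len(lines) < 3:
        raise ValueError("delimited spectrum needs a header and >= 2 rows")
    header = lines[0].split("\t")
    if len(header) != 2 or "wavenumber" not in header[0]:
        raise ValueError(f"malformed header {lines[0]!r}")
    kind = _KIND_ALIASES.get(header[1].strip())
    if kind is None:
        raise ValueError(f"unknown value kind {header[1]!r} in header")
    try:
        data = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric row in {path}") from exc
    w, v = data[:, 0], data[:, 1]
    if np.all(np.diff(w) < 0):
        logger.warning("descending wavenumber grid in %s; re-sorting ascending", path)
        w, v = w[::-1], v[::-1]
    return Spectrum(w, v, kind)


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_jcamp(path) -> Spectrum:
    """Minimal JCAMP-DX reader: ##XYDATA=(X++(Y..Y)) tables and
    ##XYPOINTS/##PEAK TABLE=(XY..XY) pairs, honouring XFACTOR/YFACTOR.

    Values are returned as absorbance (mOD) unless YUNITS says
    REFLECTANCE.
    """
    path = Path(path)
    fields: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    mode = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key in ("XYDATA", "XYPOINTS", "PEAK TABLE"):
                mode = "xy" if "XY..XY" in value.upper() else "x++y"
            elif key == "END":
                mode = None
            else:
                fields[key] = value
            continue
        if mode is None:
            continue
        nums = [float(m) for m in _JCAMP_NUM.findall(line)]
        if not nums:
            continue
        if mode == "x++y":
            xs.append(nums[0])
            ys.extend(nums[1:])
        else:
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])

    xf = float(fields.get("XFACTOR", 1.0))
    yf = float(fields.get("YFACTOR", 1.0))
    if mode == "xy" or len(xs) == len(ys):
        w = np.asarray(xs) * xf
        v = np.asarray(ys) * yf
    else:
        # (X++(Y..Y)): xs are per-line leading abscissae; rebuild grid
        n = len(ys)
        first = float(fields["FIRSTX"])
        last = float(fields["LASTX"])
        npoints = int(fields.get("NPOINTS", n))
        if npoints != n:
            raise ValueError(f"JCAMP NPOINTS={npoints} but {n} ordinates read")
        w = np.linspace(first, last, n) * xf
        v = np.asarray(ys) * yf
    if w[0] > w[-1]:
        logger.warning("descending JCAMP grid in %s; re-sorting ascending", path)
        w, v = w[::-1], v[::-1]
    yunits = fields.get("YUNITS", "").upper()
    kind = REFLECTANCE if "REFLECTANCE" in yunits else ABSORBANCE_MOD
    return Spectrum(w, v, kind)


# --------------------------------------------------------------------------
# datasets


def save_dataset(ds: SyntheticDataset, directory) -> None:
    """Store a dataset as delimited text: spectra matrix, truth table,
    times, and a YAML metadata file."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "spectra.tsv", ds.spectra, delimiter="\t", fmt="%.17e")
    np.savetxt(
        d / "truth.tsv",
        ds.weights,
        delimiter="\t",
        fmt="%.17e",
        header="\t".join(SPECIES),
        comments="",
    )
    np.savetxt(d / "grid.tsv", ds.grid, fmt="%.17e")
    np.savetxt(d / "times_min.tsv", ds.times, fmt="%.17e")
    meta = {
        "platform": ds.platform,
        "sigma_mOD": float(ds.sigma),
        "drift_max_mOD": float(ds.drift_max),
        "seed": int(ds.seed),
        "n_rows": int(ds.n_rows),
        "species": list(SPECIES),
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_dataset(directory) -> SyntheticDataset:
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    return SyntheticDataset(
        grid=np.loadtxt(d / "grid.tsv"),
        spectra=np.loadtxt(d / "spectra.tsv", delimiter="\t"),
        weights=np.loadtxt(d / "truth.tsv", delimiter="\t", skiprows=1),
        platform=meta["platform"],
        sigma=meta["sigma_mOD"],
        seed=meta["seed"],
        times=np.loadtxt(d / "times_min.tsv"),
        drift_max=meta.get("drift_max_mOD", 10.0),
    )


# --------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Validated experiment configuration; every block is optional and
    falls back to the package defaults."""

    seed: int = 0
    platform: str = "spphp"
    out_dir: str = "results"
    grid: dict = field(default_factory=dict)
    dielectric: DielectricModel | None = None
    system: CoupledSystem | None = None
    kinetics: KineticsParams | None = None
    signatures: dict[str, ReactantSignature] | None = None
    noise: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.platform not in ("spphp", "nanorod"):
            raise ValueError(f"unknown platform {self.platform!r}")


_TOP_KEYS = {
    "seed",
    "platform",
    "out_dir",
    "grid",
    "dielectric",
    "system",
    "kinetics",
    "signatures",
    "noise",
    "network",
}


def _build_dielectric(block: dict) -> DielectricModel:
    oscs = tuple(
        LorentzOscillator(o["strength"], o["center"], o["damping"])
        for o in block.get("oscillators", [])
    )
    return DielectricModel(block["eps_inf"], oscs)


def _build_system(block: dict) -> CoupledSystem:
    return CoupledSystem(
        lspp=PolaritonMode(block["lspp"]["omega"], block["lspp"]["gamma"]),
        sphp=PolaritonMode(block["sphp"]["omega"], block["sphp"]["gamma"]),
        g=block.get("g"),
        kappa=block.get("kappa"),
    )


def _build_signatures(block: dict) -> dict[str, ReactantSignature]:
    out = {}
    for name, spec_ in block.items():
        bands = tuple(
            VibrationalBand(b["center"], b["fwhm"], b["absorptivity"])
            for b in spec_["bands"]
        )
        out[name] = ReactantSignature(
            name, bands, spec_["refractive_increment"], spec_["ref_max"]
        )
    return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are
    rejected before any computation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        platform=raw.get("platform", "spphp"),
        out_dir=raw.get("out_dir", "results"),
        grid=raw.get("grid", {}),
        noise=raw.get("noise", {}),
        network=raw.get("network", {}),
    )
    if "dielectric" in raw:
        cfg.dielectric = _build_dielectric(raw["dielectric"])
    if "system" in raw:
        cfg.system = _build_system(raw["system"])
    if "kinetics" in raw:
        cfg.kinetics = KineticsParams(**raw["kinetics"])
    if "signatures" in raw:
        cfg.signatures = _build_signatures(raw["signatures"])
    return cfg


def manifest(cfg_payload: dict, seed: int) -> dict:
    """Run manifest: canonical config hash, seed, library versions."""
    import scipy
    import sklearn

    from . import __version__

    blob = yaml.safe_dump(cfg_payload, sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "versions": {
            "spphp": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
    }


def write_manifest(payload: dict, seed: int, path) -> None:
    Path(path).write_text(json.dumps(manifest(payload, seed), indent=2, sort_keys=True))
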