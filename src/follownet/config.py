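"""Run configuration, shipped per-system defaults, seeds and serialization.

One global seed expands deterministically into independent streams for tuning,
decoder samples, command input, and noise/perturbations, so a run is
reproducible from a single integer.  Run artifacts are written to a directory
with a manifest of SHA-256 checksums; loading refuses tampered files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["SYSTEM_TABLE", "RunConfig", "load_config", "save_run", "load_run",
           "expand_seed"]


#: Shipped full-scale parameters per reference system (network sizes,
#: representation radii, babbling amplitudes, pedestal periods, learning rate).
#: zeta values may be per-command-component tuples.
SYSTEM_TABLE: dict[str, dict] = {
    "linear": dict(
        n_neurons=2000, t_period=2.0, radius_cmd=0.2, radius_rec=1.0,
        zeta1=0.2 / 6, zeta2=1.0 / 16, eta=2e-4, kick_only=False,
        interpolate=False,
    ),
    "vdp": dict(
        n_neurons=3000, t_period=4.0, radius_cmd=0.2, radius_rec=5.0,
        zeta1=(0.2 / 6, 0.2 / 2), zeta2=(0.2 / 6, 0.2 / 2), eta=2e-4,
        kick_only=False, interpolate=False,
    ),
    "lorenz": dict(
        n_neurons=5000, t_period=20.0, radius_cmd=6.0, radius_rec=30.0,
        zeta1=30.0 / 10, zeta2=0.0, eta=2e-4, kick_only=True,
        interpolate=False,
    ),
    "arm": dict(
        n_neurons=5000, t_period=2.0, radius_cmd=0.2, radius_rec=1.0,
        zeta1=1.0 / 0.3, zeta2=1.0 / 0.3, eta=2e-4, kick_only=False,
        interpolate=True,
    ),
    "ff_nonlinear": dict(
        n_neurons=2000, t_period=2.0, radius_cmd=0.2, radius_rec=1.0,
        zeta1=0.2 / 0.6, zeta2=1.0 / 1.6, eta=2e-4, kick_only=False,
        interpolate=False,
    ),
}

#: Full-scale Fig.-2-style non-linear-oscillator protocol: fixed-gain tuning,
#: 5,000 s of learning with the rate boosted x20 after 1,000 s.
FIG2_FULLSCALE = dict(
    system="vdp", n_neurons=3000, tuning_scheme="fixed_gain",
    t_pre=4.0, t_learn=5000.0, t_test=16.0,
    eta=2e-4, eta_schedule=[(1000.0, 20.0)], k=10.0,
)


@dataclass
class RunConfig:
    """Declarative description of one learning run."""

    system: str = "vdp"
    n_neurons: int | None = None          # None -> Table default
    n_cmd_neurons: int | None = None      # None -> same as n_neurons
    tuning_scheme: str = "intercept_maxrate"
    radius_cmd: float | None = None
    radius_rec: float | None = None
    k: float = 10.0
    eta: float | None = None
    eta_schedule: list | None = None
    tau_s: float = 0.020
    tau_eps: float = 0.200
    dt: float = 1e-3
    t_pre: float = 4.0
    t_learn: float = 500.0
    t_test: float = 16.0
    zeta1: float | list | None = None
    zeta2: float | list | None = None
    t_period: float | None = None
    connectivity: float = 1.0
    decoder_chi: float = 0.0
    decoder_xi: float = 0.0
    error_noise_sigma: float = 0.0
    reference_delay: float = 0.0
    compensate_command_delay: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.system not in SYSTEM_TABLE:
            raise ValueError(f"unknown system {self.system!r}")
        table = SYSTEM_TABLE[self.system]
        for cfg_key, tab_key in [
            ("n_neurons", "n_neurons"), ("radius_cmd", "radius_cmd"),
            ("radius_rec", "radius_rec"), ("eta", "eta"),
            ("zeta1", "zeta1"), ("zeta2", "zeta2"), ("t_period", "t_period"),
        ]:
            if getattr(self, cfg_key) is None:
                setattr(self, cfg_key, table[tab_key])
        if self.n_cmd_neurons is None:
            self.n_cmd_neurons = self.n_neurons
        if not 0.0 < self.connectivity <= 1.0:
            raise ValueError("connectivity must be in (0, 1]")
        for name in ("dt", "tau_s", "tau_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**raw)


def expand_seed(seed: int, n: int = 4) -> list[np.random.Generator]:
    """Expand one global seed into ``n`` independent generators
    (tuning, decoder samples, input, noise — in that order by convention)."""
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_run(outdir, config: RunConfig, weights=None, metrics: dict | None = None,
             arrays: dict | None = None) -> Path:
    """Write a run directory: config, optional weights/metrics/arrays, and a
    checksum manifest.  Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    written.append(cfg_path)

    if weights is not None:
        wpath = outdir / "weights.npz"
        weights.to_npz(wpath)
        written.append(wpath)
    if arrays:
        apath = outdir / "arrays.npz"
        np.savez(apath, **arrays)
        written.append(apath)
    if metrics:
        for name, table in metrics.items():
            mpath = outdir / f"{name}.csv"
            arr = np.atleast_2d(np.asarray(table))
            np.savetxt(mpath, arr, delimiter=",")
            written.append(mpath)

    manifest = {
        "config_hash": _sha256(cfg_path),
        "files": {p.name: _sha256(p) for p in written},
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def load_run(outdir) -> dict:
    """Load a run directory, verifying every checksum in the manifest."""
    from .network import WeightSet

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        actual = _sha256(outdir / name)
        if actual != digest:
            raise ValueError(f"checksum mismatch for {name}: run dir corrupted")
    out: dict = {"config": load_config(outdir / "config.yaml")}
    if (outdir / "weights.npz").exists():
        out["weights"] = WeightSet.from_npz(outdir / "weights.npz")
    if (outdir / "arrays.npz").exists():
        with np.load(outdir / "arrays.npz", allow_pickle=False) as f:
            out["arrays"] = {k: f[k] for k in f.files}
    return out
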