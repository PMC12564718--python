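"""Run configuration resolution and manifest logging.

Every CLI command resolves its parameters as: built-in defaults,
overridden by a YAML config file, overridden by command-line flags —
and records the fully resolved set, the seed, the package version and
content digests of input files in a JSON run manifest next to the
artifacts. All randomness in a run fans out from the single manifest
seed.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path

import yaml


class UnknownConfigKeyError(ValueError):
    pass


def resolve_config(defaults: dict, yaml_file: str | Path | None = None,
                   flag_overrides: dict | None = None) -> dict:
    """Merge defaults ← YAML file ← flags; unknown keys raise, listing
    the offending names (so a typo like 'learnign_rate' fails loudly)."""
    resolved = dict(defaults)

    def apply(source: dict, origin: str):
        unknown = [k for k in source if k not in defaults]
        if unknown:
            raise UnknownConfigKeyError(
                f"unknown configuration key(s) from {origin}: {', '.join(sorted(unknown))}")
        for k, v in source.items():
            if v is not None:
                resolved[k] = v

    if yaml_file is not None:
        loaded = yaml.safe_load(Path(yaml_file).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a YAML mapping")
        apply(loaded, str(yaml_file))
    if flag_overrides:
        apply(flag_overrides, "command line")
    return resolved


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class RunManifest:
    """Collects run metadata and writes exactly one manifest JSON."""

    def __init__(self, command: str, config: dict, seed: int,
                 inputs: list[str | Path] = ()):
        from . import __version__
        self.data = {
            "command": command,
            "config_snapshot": {k: (str(v) if isinstance(v, Path) else v)
                                for k, v in config.items()},
            "seed": seed,
            "package_version": __version__,
            "input_digests": {str(p): file_digest(p) for p in inputs},
            "started": dt.datetime.now(dt.timezone.utc).isoformat(),
        }

    def finish(self, out_dir: str | Path, extra: dict | None = None) -> Path:
        self.data["finished"] = dt.datetime.now(dt.timezone.utc).isoformat()
        if extra:
            self.data.update(extra)
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, default=str))
        return path
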