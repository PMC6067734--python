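"""Config-file-driven invocation of an arbitrary external aligner.

The tool never links against an aligner: it launches an unmodified aligner
binary as a child process, substituting FIFO paths into a command template.
Each supported aligner is described by a small YAML file (shipped under
``splitalign/configs/``) so that a changed or new aligner interface needs a
config edit, not a code change.  Only long-stable options are used in the
shipped configs, keeping the adapter version-agnostic with respect to the
aligner.
"""

from __future__ import annotations

import shlex
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import yaml

from .seqformats import SeqFormat

__all__ = [
    "AlignerSpec",
    "ConfigError",
    "load_aligner_spec",
    "builtin_config_path",
    "build_command",
]

_PLACEHOLDERS = {"index", "input1", "input2", "output", "threads", "format"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AlignerSpec:
    """How to invoke one external aligner.

    Templates are whitespace-tokenized argument strings over the placeholder
    set ``{index} {input1} {input2} {output} {threads} {format}``; tokens
    that substitute to the empty string are dropped.  ``stdout_mode`` means
    the aligner writes SAM to standard output instead of an ``{output}``
    path.
    """

    name: str
    executable: str
    single_end_template: str
    paired_end_template: str
    format_flags: Dict[SeqFormat, str] = field(default_factory=dict)
    stdout_mode: bool = False
    memory_per_instance: Optional[int] = None

    def __post_init__(self) -> None:
        for label, template in (
            ("single_end_template", self.single_end_template),
            ("paired_end_template", self.paired_end_template),
        ):
            names = _placeholder_names(template, label)
            unknown = names - _PLACEHOLDERS
            if unknown:
                raise ConfigError(
                    f"{label}: unknown placeholder(s) {sorted(unknown)}"
                )
            if "input1" not in names:
                raise ConfigError(f"{label} must contain {{input1}}")
            if "output" not in names and not self.stdout_mode:
                raise ConfigError(
                    f"{label} must contain {{output}} unless stdout_mode is set"
                )
            if self.stdout_mode and "output" in names:
                raise ConfigError(f"{label} contains {{output}} but stdout_mode is set")
        if "input2" not in _placeholder_names(self.paired_end_template, "paired"):
            raise ConfigError("paired_end_template must contain {input2}")


def _placeholder_names(template: str, label: str) -> set:
    try:
        return {f for _, f, _, _ in string.Formatter().parse(template) if f}
    except ValueError as exc:
        raise ConfigError(f"{label}: malformed template: {exc}") from exc


_MANDATORY = ("name", "executable", "single_end_template", "paired_end_template")


def load_aligner_spec(config_path: Union[str, Path]) -> AlignerSpec:
    """Load and validate an aligner description from a YAML config file."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{config_path}: config must be a mapping")
    for key in _MANDATORY:
        if key not in raw or raw[key] in (None, ""):
            raise ConfigError(f"{config_path}: missing mandatory field {key!r}")
    fmt_flags: Dict[SeqFormat, str] = {}
    for k, v in (raw.get("format_flags") or {}).items():
        try:
            fmt = SeqFormat[k.upper()]
        except KeyError:
            raise ConfigError(f"{config_path}: unknown format {k!r} in format_flags") from None
        fmt_flags[fmt] = str(v) if v is not None else ""
    mem = raw.get("memory_per_instance")
    return AlignerSpec(
        name=str(raw["name"]),
        executable=str(raw["executable"]),
        single_end_template=str(raw["single_end_template"]),
        paired_end_template=str(raw["paired_end_template"]),
        format_flags=fmt_flags,
        stdout_mode=bool(raw.get("stdout_mode", False)),
        memory_per_instance=int(mem) if mem is not None else None,
    )


def builtin_config_path(name: str) -> Path:
    """Path of a shipped aligner config (``mock`` or ``hisat2``)."""
    ref = resources.files("splitalign") / "configs" / f"{name}.yaml"
    path = Path(str(ref))
    if not path.exists():
        raise ConfigError(f"no builtin aligner config named {name!r}")
    return path


def build_command(
    spec: AlignerSpec,
    mode: str,
    fmt: SeqFormat,
    index: Union[str, Path],
    inputs: Sequence[Union[str, Path]],
    output: Optional[Union[str, Path]],
    threads: int = 1,
) -> List[str]:
    """Pure textual substitution of placeholders into the mode's template.

    Returns the full argument vector, executable first.  Deterministic; no
    placeholder survives substitution.
    """
    if mode not in ("single", "paired"):
        raise ValueError(f"mode must be 'single' or 'paired', got {mode!r}")
    expected = 1 if mode == "single" else 2
    if len(inputs) != expected:
        raise ValueError(f"{mode} mode needs {expected} input(s), got {len(inputs)}")
    if threads < 1:
        raise ValueError(f"threads must be >= 1, got {threads}")
    template = spec.single_end_template if mode == "single" else spec.paired_end_template
    values = {
        "index": str(index),
        "input1": str(inputs[0]),
        "input2": str(inputs[1]) if len(inputs) > 1 else "",
        "output": str(output) if output is not None else "",
        "threads": str(threads),
        "format": spec.format_flags.get(fmt, ""),
    }
    argv = shlex.split(spec.executable)
    for token in template.split():
        substituted = token.format(**values)
        if substituted:
            argv.append(substituted)
    return argv
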