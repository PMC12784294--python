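"""Minimal TOML dump/load for plain-text configs.

The stdlib ships a TOML reader (``tomllib``) but no writer; this module
adds the small writer needed for config round-trips: scalars, lists,
nested tables and arrays of inline tables.
"""

from __future__ import annotations

import tomllib


def _fmt_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    raise TypeError(f"cannot serialize {type(value).__name__} to TOML")


def _fmt_key(key) -> str:
    key = str(key)
    if key and all(ch.isalnum() or ch in "-_" for ch in key):
        return key
    return _fmt_scalar(key)


def _fmt_value(value) -> str:
    if isinstance(value, dict):
        inner = ", ".join(f"{_fmt_key(k)} = {_fmt_value(v)}" for k, v in value.items())
        return "{ " + inner + " }"
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_fmt_value(v) for v in value) + "]"
    return _fmt_scalar(value)


def dumps(data: dict, _path: tuple = ()) -> str:
    lines: list[str] = []
    tables: list[tuple[tuple, dict]] = []
    for key, value in data.items():
        if isinstance(value, dict):
            tables.append((_path + (key,), value))
        else:
            lines.append(f"{_fmt_key(key)} = {_fmt_value(value)}")
    chunks = ["\n".join(lines)] if lines else []
    for path, value in tables:
        header = ".".join(_fmt_key(p) for p in path)
        chunks.append(f"[{header}]\n" + dumps(value, _path=path))
    return "\n\n".join(chunk for chunk in chunks if chunk.strip())


def dump(data: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps(data).strip() + "\n")


def load(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)
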