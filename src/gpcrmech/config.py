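"""Plain-text ``key = value`` configuration files.

Values are parsed as int, float, bool or comma-separated lists thereof;
anything else stays a string.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations


def _coerce(text: str):
    text = text.strip()
    if "," in text:
        return [_coerce(part) for part in text.split(",")]
    low = text.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def read_config(path: str) -> dict:
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = _coerce(value)
    return out


def write_config(path: str, values: dict) -> None:
    with open(path, "w") as fh:
        for key, value in values.items():
            if isinstance(value, (list, tuple)):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key} = {value}\n")
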