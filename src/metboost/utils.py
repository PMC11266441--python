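"""Small shared helpers for environment identifiers."""

from __future__ import annotations


def field_location(env: str) -> str:
    """Field location = environment name without its trailing year."""
    return str(env).rsplit("_", 1)[0]


def env_year(env: str) -> int:
    """Trial year parsed from an environment id like ``L03_2020``."""
    return int(str(env).rsplit("_", 1)[1])
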