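"""YAML run configuration: parsing, validation, unit conversion.

Interface units match common protocol notation — frequencies in Hz, times
in milliseconds, T2b in microseconds; everything is converted to strict SI
(rad/s, s) at parse time.  Unknown keys are rejected so typos fail loudly,
and a parsed configuration round-trips through ``to_dict``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .inversion import InversionConfig
from .params import (
    PRESETS,
    LineshapeKind,
    PulseTrainParams,
    RfPair,
    TwoPoolParams,
)


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    pools: TwoPoolParams
    rf_pair: RfPair
    train: PulseTrainParams
    estimator: str
    inversion: InversionConfig | None
    seed: int
    output_dir: str
    raw: dict

    def to_dict(self) -> dict:
        return self.raw


def _parse_tissue(section: dict) -> TwoPoolParams:
    _check_keys(
        section,
        {"preset", "t1a_ms", "t2a_ms", "t2b_us", "fb", "kba", "t1b_ms", "lineshape"},
        "tissue",
    )
    if "preset" in section:
        name = section["preset"]
        if name not in PRESETS:
            raise ConfigError(
                f"unknown tissue preset {name!r}; available: {sorted(PRESETS)}"
            )
        pools = PRESETS[name]()
        overrides = {k: v for k, v in section.items() if k != "preset"}
    else:
        required = {"t1a_ms", "t2a_ms", "t2b_us", "fb", "kba"}
        missing = required - set(section)
        if missing:
            raise ConfigError(f"tissue section missing keys: {sorted(missing)}")
        pools = TwoPoolParams.from_times(
            T1a=section["t1a_ms"] * 1e-3,
            T2a=section["t2a_ms"] * 1e-3,
            T2b=section["t2b_us"] * 1e-6,
            fb=section["fb"],
            kba=section["kba"],
            T1b=section.get("t1b_ms", None)
            and section["t1b_ms"] * 1e-3,
            lineshape=LineshapeKind(
                section.get("lineshape", "super_lorentzian")
            ),
        )
        overrides = {}
    if overrides:
        kw = {}
        if "t1a_ms" in overrides:
            kw["R1a"] = 1e3 / overrides["t1a_ms"]
        if "t2a_ms" in overrides:
            kw["R2a"] = 1e3 / overrides["t2a_ms"]
        if "t1b_ms" in overrides:
            kw["R1b"] = 1e3 / overrides["t1b_ms"]
        if "t2b_us" in overrides:
            kw["T2b"] = overrides["t2b_us"] * 1e-6
        if "fb" in overrides:
            kw["fb"] = overrides["fb"]
        if "kba" in overrides:
            kw["kba"] = overrides["kba"]
        if "lineshape" in overrides:
            kw["lineshape"] = LineshapeKind(overrides["lineshape"])
        pools = pools.with_(**kw)
    return pools


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"empty or malformed config file: {path}")
    _check_keys(
        raw,
        {"tissue", "rf_pair", "train", "estimator", "inversion", "seed", "output_dir"},
        "top level",
    )
    for required in ("tissue", "rf_pair", "train"):
        if required not in raw:
            raise ConfigError(f"config missing required section {required!r}")

    pools = _parse_tissue(dict(raw["tissue"]))

    rf = dict(raw["rf_pair"])
    _check_keys(rf, {"f1_lo_hz", "offset_lo_hz", "f1_hi_hz", "offset_hi_hz"}, "rf_pair")
    try:
        rf_pair = RfPair.from_hz(
            rf["f1_lo_hz"], rf["offset_lo_hz"], rf["f1_hi_hz"], rf["offset_hi_hz"]
        )
    except KeyError as err:
        raise ConfigError(f"rf_pair missing key {err}") from err
    except ValueError as err:
        raise ConfigError(str(err)) from err

    tr = dict(raw["train"])
    _check_keys(tr, {"tp_ms", "tf_ms", "n"}, "train")
    try:
        train = PulseTrainParams.from_ms(tr["tp_ms"], tr["tf_ms"], tr["n"])
    except (KeyError, ValueError) as err:
        raise ConfigError(f"invalid train section: {err}") from err

    estimator = raw.get("estimator", "four_image")
    if estimator not in ("four_image", "fit"):
        raise ConfigError(f"estimator must be 'four_image' or 'fit', got {estimator!r}")

    inversion = None
    if "inversion" in raw:
        inv = dict(raw["inversion"])
        _check_keys(
            inv,
            {"kba", "t2b_us", "lineshape", "mode", "fb_min", "fb_max", "r1b"},
            "inversion",
        )
        try:
            inversion = InversionConfig(
                kba=inv.get("kba", pools.kba),
                T2b=inv.get("t2b_us", pools.T2b * 1e6) * 1e-6,
                lineshape=LineshapeKind(
                    inv.get("lineshape", pools.lineshape.value)
                ),
                mode=inv.get("mode", "root_find_analytic"),
                fb_min=inv.get("fb_min", 0.0),
                fb_max=inv.get("fb_max", 0.3),
                r1b=inv.get("r1b", None),
            )
        except ValueError as err:
            raise ConfigError(str(err)) from err

    seed = int(raw.get("seed", 0))
    return RunConfig(
        pools=pools,
        rf_pair=rf_pair,
        train=train,
        estimator=estimator,
        inversion=inversion,
        seed=seed,
        output_dir=str(raw.get("output_dir", "mpfpsl_out")),
        raw=raw,
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the configuration back to YAML (round-trips with parse_config)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
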