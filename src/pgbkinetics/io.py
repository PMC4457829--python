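"""Delimited-text readers and writers and key-value configuration files.

Dialect: comma-separated, ``.`` decimal, UTF-8, ``#`` starts a comment line.
Traces are ``time_s,signal`` tables; spectra tables have a ``wavelength_nm``
first column and one column per delay time (header = the delay in seconds).
Rate/config files are ``name = value`` lines; fit configs add ``fix:``,
``tie:`` and ``derive:`` sections.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .exceptions import ParseError
from .fit import FitSpec
from .kinetics import KineticTrace
from .rates import RATE_FIELDS, ExperimentConditions, RateConstants
from .svd import SpectraMatrix

_FMT = "%.17g"  # lossless for float64

_CONDITION_KEYS = ("co_pressure", "temperature", "co_solubility", "photolysis_yield",
                   "scavenger_mode")


def _data_lines(path):
    """Yield (line_number, stripped_text) for non-comment, non-blank lines."""
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            text = raw.strip()
            if not text or text.startswith("#"):
                continue
            yield lineno, text


def read_trace(path) -> KineticTrace:
    """Read a ``time_s,signal`` trace file."""
    rows = []
    header_seen = False
    for lineno, text in _data_lines(path):
        if not header_seen:
            cols = [c.strip() for c in text.split(",")]
            if cols != ["time_s", "signal"]:
                raise ParseError(f"expected header 'time_s,signal', got {text!r}",
                                 line=lineno, path=str(path))
            header_seen = True
            continue
        cols = text.split(",")
        if len(cols) != 2:
            raise ParseError(f"expected 2 columns, got {len(cols)}", line=lineno, path=str(path))
        try:
            rows.append((float(cols[0]), float(cols[1])))
        except ValueError:
            raise ParseError(f"non-numeric row {text!r}", line=lineno, path=str(path)) from None
    if not header_seen:
        raise ParseError("empty trace file", line=1, path=str(path))
    data = np.asarray(rows)
    times, signal = data[:, 0], data[:, 1]
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0])
        raise ParseError(f"times not strictly increasing at row {bad + 2}", path=str(path))
    return KineticTrace(times=times, signal=signal)


def write_trace(trace: KineticTrace, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("time_s,signal\n")
        for t, s in zip(trace.times, trace.signal):
            handle.write(f"{t:.17g},{s:.17g}\n")


def read_spectra(path) -> SpectraMatrix:
    """Read a spectra table (first column ``wavelength_nm``, remaining column
    headers the delay times in seconds)."""
    header = None
    rows = []
    for lineno, text in _data_lines(path):
        cols = [c.strip() for c in text.split(",")]
        if header is None:
            if cols[0] != "wavelength_nm" or len(cols) < 2:
                raise ParseError(
                    f"expected header 'wavelength_nm,<delays...>', got {text!r}",
                    line=lineno, path=str(path))
            try:
                header = [float(c) for c in cols[1:]]
            except ValueError:
                raise ParseError("non-numeric delay time in header", line=lineno,
                                 path=str(path)) from None
            continue
        if len(cols) != len(header) + 1:
            raise ParseError(
                f"ragged row: expected {len(header) + 1} columns, got {len(cols)}",
                line=lineno, path=str(path))
        try:
            rows.append([float(c) for c in cols])
        except ValueError:
            raise ParseError(f"non-numeric row {text!r}", line=lineno, path=str(path)) from None
    if header is None:
        raise ParseError("empty spectra file", line=1, path=str(path))
    if not rows:
        raise ParseError("spectra file has no data rows", path=str(path))
    data = np.asarray(rows)
    return SpectraMatrix(
        wavelengths=data[:, 0], delay_times=np.asarray(header), values=data[:, 1:]
    )


def write_spectra(m: SpectraMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("wavelength_nm," + ",".join(f"{t:.17g}" for t in m.delay_times) + "\n")
        for wl, row in zip(m.wavelengths, m.values):
            handle.write(f"{wl:.17g}," + ",".join(f"{v:.17g}" for v in row) + "\n")


def _parse_keyvalue(path) -> tuple[dict, dict]:
    """Parse a ``name = value`` file with optional ``section:`` headers.

    Returns (top-level dict, {section: list of raw lines with line numbers}).
    """
    top = {}
    sections: dict[str, list] = {}
    current = None
    for lineno, text in _data_lines(path):
        if text.endswith(":") and "=" not in text:
            current = text[:-1].strip().lower()
            sections.setdefault(current, [])
            continue
        if current is not None:
            sections[current].append((lineno, text))
            continue
        if "=" not in text:
            raise ParseError(f"expected 'name = value', got {text!r}", line=lineno,
                             path=str(path))
        name, _, value = text.partition("=")
        top[name.strip()] = (lineno, value.strip())
    return top, sections


def _to_number(raw, lineno, path):
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"non-numeric value {raw!r}", line=lineno, path=str(path)) from None


def read_rates_config(path) -> tuple[RateConstants, ExperimentConditions, dict]:
    """Read rate constants plus optional conditions from a key-value file.

    Keys are the rate-constant field names; condition keys (``co_pressure``,
    ``temperature``, ``co_solubility``, ``photolysis_yield``,
    ``scavenger_mode``) are optional and default to the standard photolysis
    conditions.  Any remaining keys (e.g. ``koff_slow``) are returned in the
    extras dict.
    """
    top, sections = _parse_keyvalue(path)
    if sections:
        raise ParseError(f"unexpected section(s) {sorted(sections)} in rates file",
                         path=str(path))
    rate_values = {}
    cond_values = {}
    extras = {}
    for name, (lineno, raw) in top.items():
        if name in RATE_FIELDS:
            rate_values[name] = _to_number(raw, lineno, path)
        elif name in _CONDITION_KEYS:
            if name == "scavenger_mode":
                cond_values[name] = raw.lower() in ("1", "true", "yes")
            else:
                cond_values[name] = _to_number(raw, lineno, path)
        else:
            extras[name] = _to_number(raw, lineno, path)
    missing = set(RATE_FIELDS) - set(rate_values)
    if missing:
        raise ParseError(f"missing rate constants: {', '.join(sorted(missing))}",
                         path=str(path))
    return RateConstants(**rate_values), ExperimentConditions(**cond_values), extras


def write_rates_config(rates: RateConstants, path, conditions: ExperimentConditions | None = None,
                       extras: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# microscopic rate constants (kin_r/kin_t in M^-1 s^-1, others s^-1)\n")
        handle.write("# kd2/k_d2 are the t-state primary<->secondary docking-site migration rates\n")
        handle.write("# (often written kd/k-d); kdiss_r/kdiss_t are the thermal Fe-CO bond\n")
        handle.write("# dissociation rates (often written kd,r/kd,t)\n")
        for name, value in rates.as_dict().items():
            handle.write(f"{name} = {value:.17g}\n")
        if conditions is not None:
            handle.write("# experimental conditions\n")
            handle.write(f"co_pressure = {conditions.co_pressure:.17g}\n")
            handle.write(f"temperature = {conditions.temperature:.17g}\n")
            handle.write(f"co_solubility = {conditions.co_solubility:.17g}\n")
            handle.write(f"photolysis_yield = {conditions.photolysis_yield:.17g}\n")
            handle.write(f"scavenger_mode = {str(conditions.scavenger_mode).lower()}\n")
        for name, value in (extras or {}).items():
            handle.write(f"{name} = {value:.17g}\n")


def read_fit_config(path) -> dict:
    """Read a fit configuration: initial values at top level, plus optional
    ``fix:``, ``tie:`` and ``derive:`` sections.

    ``fix:`` lists one parameter name per line; ``tie:`` lines are
    ``target = source``; ``derive:`` lines are ``koff_r = value`` /
    ``koff_t = value`` (measured off-rates pinning kdiss_r/kdiss_t).
    Returns a dict with keys ``initial`` (name -> value), ``fixed``,
    ``ties`` and ``derived_koff`` ready for :class:`~pgbkinetics.fit.FitSpec`.
    """
    top, sections = _parse_keyvalue(path)
    unknown = set(sections) - {"fix", "tie", "derive"}
    if unknown:
        raise ParseError(f"unknown section(s): {sorted(unknown)}", path=str(path))
    initial = {}
    for name, (lineno, raw) in top.items():
        if name not in RATE_FIELDS:
            raise ParseError(f"unknown rate constant {name!r}", line=lineno, path=str(path))
        initial[name] = _to_number(raw, lineno, path)
    fixed = []
    for lineno, text in sections.get("fix", []):
        name = text.strip()
        if name not in RATE_FIELDS:
            raise ParseError(f"unknown parameter {name!r} in fix section", line=lineno,
                             path=str(path))
        fixed.append(name)
    ties = {}
    for lineno, text in sections.get("tie", []):
        if "=" not in text:
            raise ParseError(f"tie lines must be 'target = source', got {text!r}",
                             line=lineno, path=str(path))
        target, _, source = text.partition("=")
        ties[target.strip()] = source.strip()
    derived = {}
    for lineno, text in sections.get("derive", []):
        if "=" not in text:
            raise ParseError(f"derive lines must be 'koff_r|koff_t = value', got {text!r}",
                             line=lineno, path=str(path))
        name, _, raw = text.partition("=")
        name = name.strip()
        if name not in ("koff_r", "koff_t"):
            raise ParseError(f"derive key must be koff_r or koff_t, got {name!r}",
                             line=lineno, path=str(path))
        derived[name.removeprefix("koff_")] = _to_number(raw.strip(), lineno, path)
    return {"initial": initial, "fixed": frozenset(fixed), "ties": ties,
            "derived_koff": derived}


def build_fit_spec(config: dict, data, defaults: RateConstants | None = None) -> FitSpec:
    """Assemble a :class:`FitSpec` from a parsed fit config and trace data."""
    values = defaults.as_dict() if defaults is not None else {n: 0.0 for n in RATE_FIELDS}
    values.update(config["initial"])
    return FitSpec(
        initial=RateConstants(**values),
        data=list(data),
        fixed=config.get("fixed", frozenset()),
        ties=config.get("ties", {}),
        derived_koff=config.get("derived_koff", {}),
    )


def write_fit_report(result, path, scan: dict | None = None) -> None:
    """Write a fitted-parameter report as a key-value file."""
    scan = scan or result.scan or {}
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# global fit report\n")
        handle.write(f"rss = {result.rss:.17g}\n")
        handle.write(f"converged = {str(result.converged).lower()}\n")
        for name, value in result.rates.as_dict().items():
            handle.write(f"{name} = {value:.17g}\n")
        for name in result.free_names:
            if name in result.param_sigma:
                handle.write(f"sigma_matrix_{name} = {result.param_sigma[name]:.17g}\n")
            if name in scan:
                se = scan[name]
                handle.write(f"scan_error_{name} = {se.halfwidth:.17g}\n")
                if se.weak:
                    handle.write(f"# {name} is weakly identified\n")
        for message in result.warnings:
            handle.write(f"# warning: {message}\n")


def write_residual_table(result_traces, path) -> None:
    """Write a delimited residual table: time, data, model, residual per trace."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("trace,time_s,data,model,residual\n")
        for idx, (times, data, model) in enumerate(result_traces):
            for t, d, m in zip(times, data, model):
                handle.write(f"{idx},{t:.17g},{d:.17g},{m:.17g},{m - d:.17g}\n")
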