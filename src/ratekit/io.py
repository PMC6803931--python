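"""Readers and writers: rate tables, species/system specs, fit reports.

Dialects
--------
* Rate tables are delimited text (comma and/or whitespace), ``#`` comments,
  with a header row naming a temperature column (``T``, ``T_K``,
  ``temperature``...) and a rate column (``k``, ``rate``...), optionally a
  ``sigma`` uncertainty column.  A ``# units: ...`` comment tags the rate
  units.
* Species are YAML mappings (flat keys: name, mass_amu, geometry,
  rotational_constants_cm1, sigma, frequencies_cm1, electronic_energy,
  energy_unit, degeneracy, molar_volume_cm3) or minimal Gaussian-style
  frequency logs; the log extractor is best-effort and fixture-tested — the
  structured spec file is the supported path.
* Every output file begins with ``#`` header lines recording the package
  version, seed, input hashes and resolved parameters (never timestamps, so
  seeded runs are bitwise reproducible on disk).
"""

from __future__ import annotations

import hashlib
import re
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import InputError
from .fitting import FitResult
from .laws import LAW_PARAM_NAMES, RateLaw, eval_rate_law, params_to_dict
from .solution import SolventModel, WATER, solvent_from_mapping
from .transitivity import RateSeries, TransitivitySeries
from .tst import Geometry, ReactionSystem, Species

__all__ = [
    "read_rate_table",
    "write_rate_table",
    "load_species",
    "species_to_mapping",
    "species_from_mapping",
    "parse_gaussian_log",
    "load_system",
    "load_solvent",
    "write_fit_report",
    "write_transitivity_table",
    "output_header",
    "sha256_of",
]

_SPLIT = re.compile(r"[,\s;]+")

_T_NAMES = {"t", "t_k", "t/k", "temp", "temperature", "temperature_k"}
_K_NAMES = {"k", "rate", "k_obs", "rate_constant"}
_SIGMA_NAMES = {"sigma", "err", "error", "uncertainty", "dk"}

LAW_DISPLAY = {
    RateLaw.ARRHENIUS: "Arrhenius",
    RateLaw.AM: "AM",
    RateLaw.ASCC: "ASCC",
    RateLaw.NTS: "NTS",
    RateLaw.VFT: "VFT",
}


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def output_header(meta: dict) -> str:
    """Provenance header lines for any output file (no timestamps)."""
    lines = [f"# ratekit {__version__}"]
    for key, value in meta.items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# rate tables

def read_rate_table(path) -> RateSeries:
    """Parse a delimited (T, k[, sigma]) table into a RateSeries.

    Rows are validated one by one so that malformed or non-positive entries
    are reported with their file line numbers.
    """
    path = Path(path)
    header: list[str] | None = None
    cols: dict[str, int] = {}
    units = "arbitrary"
    T, k, sigma = [], [], []
    has_sigma = False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"units\s*:\s*(.+)", line, flags=re.IGNORECASE)
            if m:
                units = m.group(1).strip()
            continue
        tokens = [t for t in _SPLIT.split(line) if t]
        if header is None:
            header = [t.lower() for t in tokens]
            for idx, name in enumerate(header):
                base = name.split("_")[0]
                if name in _T_NAMES or (base == "t" and "t" not in {h.split("_")[0] for h in header[:idx]}):
                    cols.setdefault("T", idx)
                elif name in _SIGMA_NAMES:
                    cols.setdefault("sigma", idx)
                elif name in _K_NAMES or base == "k":
                    cols.setdefault("k", idx)
                    if "_" in name and name not in _K_NAMES:
                        units = name.split("_", 1)[1].replace("_", " ")
            if "T" not in cols or "k" not in cols:
                raise InputError(
                    f"{path.name}: header must name a temperature and a rate column "
                    f"(got {tokens!r})"
                )
            has_sigma = "sigma" in cols
            continue
        try:
            values = [float(tokens[cols["T"]]), float(tokens[cols["k"]])]
            if has_sigma:
                values.append(float(tokens[cols["sigma"]]))
        except (ValueError, IndexError) as exc:
            raise InputError(f"{path.name}, line {lineno}: unparseable row {raw!r}") from exc
        if values[0] <= 0.0:
            raise InputError(f"{path.name}, line {lineno}: non-positive temperature")
        if values[1] <= 0.0:
            raise InputError(f"{path.name}, line {lineno}: non-positive rate constant")
        T.append(values[0])
        k.append(values[1])
        if has_sigma:
            sigma.append(values[2])

    if header is None or not T:
        raise InputError(f"{path.name}: no data rows found")
    return RateSeries(
        T=np.asarray(T),
        k=np.asarray(k),
        sigma=np.asarray(sigma) if has_sigma else None,
        label=path.stem,
        units=units,
    )


def write_rate_table(path, T, k, units: str, meta: dict | None = None) -> None:
    path = Path(path)
    lines = [output_header(meta or {}).rstrip("\n"), f"# units: {units}", "T_K k"]
    for t, kk in zip(np.asarray(T), np.asarray(k)):
        lines.append(f"{t:.6f} {kk:.10e}")
    path.write_text("\n".join(lines) + "\n")


def write_transitivity_table(path, ts: TransitivitySeries, meta: dict | None = None) -> None:
    """4-column (T, beta, Ea, gamma) plot-ready table."""
    path = Path(path)
    lines = [
        output_header(meta or {}).rstrip("\n"),
        f"# smoothed: {ts.smoothed}",
        "# endpoints use one-sided differences (lower accuracy)",
        "T_K beta_mol_cal Ea_cal_mol gamma_mol_cal",
    ]
    for t, b, ea, g in zip(ts.T, ts.beta, ts.Ea, ts.gamma):
        lines.append(f"{t:.6f} {b:.10e} {ea:.10e} {g:.10e}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# species / systems / solvents

_SPECIES_KEYS = {
    "name",
    "mass_amu",
    "geometry",
    "rotational_constants_cm1",
    "sigma",
    "frequencies_cm1",
    "electronic_energy",
    "energy_unit",
    "degeneracy",
    "molar_volume_cm3",
    "imaginary_cm1",
}


def species_to_mapping(sp: Species) -> dict:
    out = {
        "name": sp.name,
        "mass_amu": sp.mass_amu,
        "geometry": sp.geometry.value,
        "sigma": sp.sigma,
        "degeneracy": sp.degeneracy,
        "energy_unit": sp.energy_unit,
    }
    if sp.rotational_constants_cm1 is not None:
        out["rotational_constants_cm1"] = list(sp.rotational_constants_cm1)
    if sp.frequencies_cm1:
        out["frequencies_cm1"] = list(sp.frequencies_cm1)
    if sp.imaginary_cm1:
        out["imaginary_cm1"] = list(sp.imaginary_cm1)
    if sp.electronic_energy is not None:
        out["electronic_energy"] = sp.electronic_energy
    if sp.molar_volume_cm3 is not None:
        out["molar_volume_cm3"] = sp.molar_volume_cm3
    return out


def species_from_mapping(mapping: dict) -> Species:
    data = dict(mapping)
    bad = set(data) - _SPECIES_KEYS
    if bad:
        raise InputError(f"unknown species keys: {sorted(bad)}")
    for key in ("rotational_constants_cm1", "frequencies_cm1", "imaginary_cm1"):
        if key in data and data[key] is not None:
            data[key] = tuple(float(x) for x in data[key])
    return Species(**data)


def parse_gaussian_log(text: str, name: str = "species") -> Species:
    """Extract a Species from a minimal Gaussian-style frequency log.

    Recognized blocks: ``Multiplicity``, final ``SCF Done`` energy (hartree),
    ``Rotational constants (GHZ)``, ``Rotational symmetry number``,
    ``Frequencies --`` (negative entries are imaginary-mode magnitudes),
    ``Molecular mass`` and the ``Molar volume`` cm**3/mol parenthetical.
    """
    freqs: list[float] = []
    for m in re.finditer(r"Frequencies\s*--\s*(.+)", text):
        freqs.extend(float(x) for x in m.group(1).split())
    rot = re.search(r"Rotational constants \(GHZ\):\s*(.+)", text)
    mass = re.search(r"Molecular mass:\s*([0-9.+-Ee]+)\s*amu", text)
    mult = re.search(r"Multiplicity\s*=\s*(\d+)", text)
    sym = re.search(r"Rotational symmetry number\s+([0-9.]+)", text)
    energies = re.findall(r"SCF Done:\s*E\([^)]*\)\s*=\s*([0-9.+-EeDd]+)", text)
    vol = re.search(r"Molar volume\s*=.*\(\s*([0-9.+-Ee]+)\s*cm\*\*3/mol\)", text)
    stoich = re.search(r"Stoichiometry\s+(\S+)", text)

    if mass is None:
        raise InputError("log lacks a 'Molecular mass' line")
    if freqs and rot is None:
        raise InputError("log has a frequency block but no rotational constants: "
                         "not a valid molecule (atoms carry no frequencies)")

    if rot is None:
        geometry = Geometry.ATOM
        constants = None
    else:
        ghz = [float(x) for x in rot.group(1).split()]
        nonzero = [g for g in ghz if g > 1e-9]
        if len(set(np.round(nonzero, 6))) == 1 and len(nonzero) == 2:
            geometry = Geometry.LINEAR
            constants = (nonzero[0] / 29.9792458,)
        elif len(nonzero) >= 3:
            geometry = Geometry.NONLINEAR
            constants = tuple(g / 29.9792458 for g in nonzero[:3])
        elif len(nonzero) == 1:
            geometry = Geometry.LINEAR
            constants = (nonzero[0] / 29.9792458,)
        else:
            raise InputError("cannot classify rotor from rotational constants")
        if not freqs:
            raise InputError("molecule log lacks a frequency block")

    imaginary = tuple(abs(f) for f in freqs if f < 0.0)
    if len(imaginary) > 1:
        warnings.warn(
            f"{len(imaginary)} imaginary modes found; using the first as the "
            "barrier-crossing candidate",
            stacklevel=2,
        )
    energy = float(energies[-1].replace("D", "E").replace("d", "e")) if energies else None

    return Species(
        name=stoich.group(1) if stoich else name,
        mass_amu=float(mass.group(1)),
        geometry=geometry,
        rotational_constants_cm1=constants,
        sigma=int(float(sym.group(1))) if sym else 1,
        frequencies_cm1=tuple(f for f in freqs if f > 0.0),
        electronic_energy=energy,
        energy_unit="hartree",
        degeneracy=int(mult.group(1)) if mult else 1,
        molar_volume_cm3=float(vol.group(1)) if vol else None,
        imaginary_cm1=imaginary,
    )


def load_species(path) -> Species:
    """Load a Species from a YAML spec file or a Gaussian-style log."""
    path = Path(path)
    text = path.read_text()
    if "Frequencies --" in text or "SCF Done" in text or "Molecular mass" in text:
        return parse_gaussian_log(text, name=path.stem)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InputError(f"{path.name}: expected a YAML mapping or a frequency log")
    data.setdefault("name", path.stem)
    return species_from_mapping(data)


def _resolve_species(entry, base: Path) -> Species:
    if isinstance(entry, str):
        return load_species((base / entry) if not Path(entry).is_absolute() else entry)
    if isinstance(entry, dict):
        return species_from_mapping(entry)
    raise InputError(f"cannot interpret species entry {entry!r}")


def load_system(path) -> ReactionSystem:
    """Load a ReactionSystem YAML (reactants/ts/products inline or by file)."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise InputError(f"{path.name}: expected a YAML mapping")
    base = path.parent
    try:
        reactants = tuple(_resolve_species(e, base) for e in data["reactants"])
        ts = _resolve_species(data["ts"], base)
        nu = float(data["nu_imag_cm1"])
    except KeyError as exc:
        raise InputError(f"{path.name}: missing required key {exc}") from exc
    products = data.get("products")
    return ReactionSystem(
        reactants=reactants,
        ts=ts,
        nu_imag_cm1=nu,
        products=tuple(_resolve_species(e, base) for e in products) if products else None,
        dH_cal_mol=float(data["dH_cal_mol"]) if "dH_cal_mol" in data else None,
        energy_override=data.get("energy_override"),
    )


def load_solvent(spec) -> SolventModel:
    """'water', a YAML file path, or an inline mapping."""
    if isinstance(spec, SolventModel):
        return spec
    if isinstance(spec, str) and spec.lower() == "water":
        return WATER
    if isinstance(spec, dict):
        return solvent_from_mapping(spec)
    data = yaml.safe_load(Path(spec).read_text())
    if not isinstance(data, dict):
        raise InputError(f"{spec}: expected a YAML solvent mapping")
    return solvent_from_mapping(data)


# ---------------------------------------------------------------------------
# fit reports

def write_fit_report(result: FitResult, series: RateSeries, directory) -> Path:
    """Write "Fit_<FormulaName>.dat" plus a machine-readable YAML twin.

    The .dat report lists the law, parameter values, the chi-square and its
    residual space, the seed and evaluation count, and a per-point residual
    table; the twin holds the same content as a flat mapping.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    display = LAW_DISPLAY[result.law]
    p = result.params

    lines = [
        output_header(
            {
                "report": f"fit of the {display} formula",
                "plane": result.plane.value,
                "residual space": result.space,
                "seed": result.seed,
                "evaluations": result.n_eval,
            }
        ).rstrip("\n"),
        f"Formula: {display}",
        f"chi2 ({result.space} space, mean squared residual): {result.chi2:.6e}",
        "Parameters (energies cal/mol, temperatures K, A in data units):",
    ]
    for name in LAW_PARAM_NAMES[result.law]:
        lines.append(f"  {name:8s} = {getattr(p, name):.8g}")
    lines.append("Per-point residuals (log10 k_obs - log10 k_model):")
    lines.append("  T_K          k_obs          k_model        residual")
    model = eval_rate_law(p, series.T)
    for t, ko, km in zip(series.T, series.k, model):
        lines.append(f"  {t:10.3f} {ko:14.6e} {km:14.6e} {np.log10(ko / km):+12.4e}")

    dat = directory / f"Fit_{display}.dat"
    dat.write_text("\n".join(lines) + "\n")

    twin = {
        "law": result.law.value,
        "plane": result.plane.value,
        "space": result.space,
        "chi2": float(result.chi2),
        "seed": int(result.seed),
        "n_eval": int(result.n_eval),
        "converged": bool(result.converged),
        **{k: float(v) for k, v in params_to_dict(result.params).items() if k != "law"},
    }
    (directory / f"Fit_{display}.yml").write_text(yaml.safe_dump(twin, sort_keys=True))
    return dat
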