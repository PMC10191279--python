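"""Load packaged species parameter files (one YAML per species).

Each file mirrors the published parameter tables field-for-field: fixed
physiological rows, released-API rows, conjugated-API rows and the hepatocyte
scaling inputs.  ``load_species`` returns a validated bundle of the typed
containers defined in :mod:`nanopbpk.model`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .model import (
    ConfigurationError,
    ConjugatedApiParams,
    ReleasedApiParams,
    SpeciesPhysiology,
    rest_volume,
)

SPECIES = ("mouse", "rat", "dog", "human")


@dataclass(frozen=True)
class SpeciesBundle:
    """Everything needed to simulate and scale one species."""

    name: str
    physiology: SpeciesPhysiology
    released: ReleasedApiParams
    conjugated: ConjugatedApiParams
    cl_range: tuple[float, ...]
    ivive: dict


def _data_path(name: str) -> Path:
    return Path(str(resources.files("nanopbpk").joinpath("data", name)))


def _load_yaml(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def bundle_from_dict(raw: dict) -> SpeciesBundle:
    """Build a validated :class:`SpeciesBundle` from a parsed config mapping."""
    try:
        name = raw["species"]
        physio = SpeciesPhysiology(species_name=name, **raw["physiology"])
        rel_raw = dict(raw["released"])
        cl_range = tuple(float(c) for c in rel_raw.pop("CL_range", [rel_raw["CL"]]))
        released = ReleasedApiParams(**rel_raw)
        conj_raw = dict(raw["conjugated"])
        conj_raw.setdefault("V_NR", rest_volume(physio))
        conjugated = ConjugatedApiParams(**conj_raw)
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed species config: {exc}") from exc
    conjugated.check_rest_volume(physio)
    return SpeciesBundle(
        name=name,
        physiology=physio,
        released=released,
        conjugated=conjugated,
        cl_range=cl_range,
        ivive=dict(raw.get("ivive", {})),
    )


def load_species(species: str | Path) -> SpeciesBundle:
    """Load a packaged species (``mouse``/``rat``/``dog``/``human``) or a
    user-supplied YAML file in the same layout."""
    path = Path(species)
    if not path.suffix:
        if str(species) not in SPECIES:
            raise ConfigurationError(
                f"unknown species {species!r}; expected one of {SPECIES} "
                "or a path to a config file"
            )
        path = _data_path(f"{species}.yaml")
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    return bundle_from_dict(_load_yaml(path))


def load_reference_pk() -> dict:
    """Published plasma NCA summary rows (doses, AUCs, half-lives, CLs)."""
    return _load_yaml(_data_path("reference_pk.yaml"))


def dump_bundle(bundle: SpeciesBundle, path: str | Path) -> None:
    """Serialize a bundle back to the YAML layout consumed by load_species."""
    raw = {
        "species": bundle.name,
        "physiology": {
            k: getattr(bundle.physiology, k)
            for k in (
                "BW", "V_L", "V_S", "V_Nb", "Q_BL_i", "Q_BL_o", "Q_BS",
                "H", "fup", "BPR", "v_liver", "v_spleen",
            )
        },
        "released": {
            **{k: getattr(bundle.released, k)
               for k in bundle.released.__dataclass_fields__},
            "CL_range": list(bundle.cl_range),
        },
        "conjugated": {
            k: getattr(bundle.conjugated, k)
            for k in bundle.conjugated.__dataclass_fields__
        },
        "ivive": bundle.ivive,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
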