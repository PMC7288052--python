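"""YAML configuration for scan specifications and residue selections."""

from __future__ import annotations

from pathlib import Path

import yaml

from .peptide import BackboneClass, ScanSpec, Stereo
from .pose_io import ResidueSelection

__all__ = ["load_scan_spec", "load_selection", "dump_scan_spec"]


def load_scan_spec(path: str | Path) -> ScanSpec:
    """Read a scan spec, e.g.::

        positions: [1, 2, 3, 4]
        stereo: [R, S]
        backbone_class: beta2h
        side_chain_variants:
          1: [mTyr]
    """
    raw = yaml.safe_load(Path(path).read_text())
    return ScanSpec(
        positions=frozenset(int(p) for p in raw.get("positions", [])),
        stereo_set=frozenset(Stereo(s) for s in raw.get("stereo", ["R", "S"])),
        side_chain_variants={
            int(k): tuple(v) for k, v in (raw.get("side_chain_variants") or {}).items()
        },
        backbone_class=BackboneClass(raw.get("backbone_class", "beta2h")),
    )


def dump_scan_spec(spec: ScanSpec, path: str | Path) -> Path:
    data = {
        "positions": sorted(spec.positions),
        "stereo": sorted(s.value for s in spec.stereo_set),
        "backbone_class": spec.backbone_class.value,
        "side_chain_variants": {
            k: list(v) for k, v in spec.side_chain_variants.items()
        },
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def load_selection(path: str | Path) -> ResidueSelection:
    """Read a residue selection, e.g.::

        residue_index: 4
        atom_names: [CG, CD1, CE1, CZ, CE2, CD2]
        symmetry_groups:
          - [CG, CD1, CE1, CZ, CE2, CD2]
    """
    raw = yaml.safe_load(Path(path).read_text())
    return ResidueSelection(
        residue_index=int(raw["residue_index"]),
        atom_names=tuple(raw["atom_names"]),
        symmetry_groups=tuple(tuple(g) for g in raw.get("symmetry_groups", [])),
    )
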