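"""Self-contained model spin systems and geometry/spin config I/O.

The fixtures emulate the structural classes studied in cryptochrome
magnetoreception without shipping any external data:

* ``reference_probe`` -- a hyperfine-carrying flavin-like radical paired with
  a nucleus-free probe radical (superoxide-like Z) plus a nucleus-free
  scavenger; the lack of magnetic nuclei on the probe maximizes directional
  contrast of the partner's hyperfine anisotropy.
* ``flavin_trp_like`` -- a flavin-like radical (one axial spin-1 nitrogen
  plus one spin-1/2 proton) paired with a tryptophan-like radical (one
  spin-1 nitrogen) at the ~1.8 nm separation of the distal tryptophan.
* ``rpm_pair`` -- the bare two-radical pair for conventional
  radical-pair-mechanism comparisons.
* ``random_trio`` -- seeded random geometry and tensors for property tests.

All hyperfine magnitudes are illustrative, literature-style placeholders
chosen to have realistic scale and anisotropy; they are not fitted values
for any specific protein, and real applications should supply their own
tensors through the config reader.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import G_ELECTRON, MHZ_PER_MT
from .et_rates import ETParams, moser_dutton_rate
from .hamiltonian import (
    ExchangeSpec,
    FieldSpec,
    GTensorSpec,
    HyperfineCoupling,
    SpinSystemSpec,
    TrioGeometry,
)
from .kinetics_yields import DEFAULT_K_F, InitialState, ReactionScheme

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "make_fixture",
    "read_geometry_config",
    "write_geometry_config",
    "system_to_dict",
    "system_from_dict",
    "config_hash",
    "pdb_site_centroids",
]

FIXTURE_KINDS = ("reference_probe", "flavin_trp_like", "rpm_pair", "random_trio")

# Illustrative hyperfine tensors (MHz).  Axial flavin-N5-like magnitude and
# smaller proton/indole-nitrogen couplings; placeholders, not fitted values.
_N5_LIKE_AXIAL = np.diag([-2.0, -2.0, 47.0])
_PROTON_LIKE = np.diag([-12.0, -9.0, -6.0])
_TRP_N_LIKE = np.diag([2.0, 2.0, 18.0])
_PROBE_AXIAL_HALF = np.diag([0.0, 0.0, 47.0])


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative recipe for a synthetic model system.

    ``primary_separation`` is the distance (A) between the primary-pair
    radicals; the scavenger is placed on the perpendicular bisector of the
    primary pair at ``scavenger_distance`` (A) from its target.  The seed
    fully determines the output.
    """

    kind: str = "reference_probe"
    primary_separation: float = 18.0
    scavenger_distance: float = 10.0
    scavenged_site: int = 2
    n_probe_nuclei: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}")
        if self.primary_separation <= 0 or self.scavenger_distance <= 0:
            raise ValueError("distances must be positive")
        if self.scavenged_site not in (1, 2):
            raise ValueError("scavenged_site must be 1 or 2")
        if not 1 <= self.n_probe_nuclei <= 2:
            raise ValueError("n_probe_nuclei must be 1 or 2")


@dataclass(frozen=True)
class FixtureBundle:
    """A fixture system with matching reaction-scheme and initial-state defaults."""

    system: SpinSystemSpec
    scheme: ReactionScheme
    init: InitialState


def _bisector_position(separation: float, distance: float) -> np.ndarray:
    """Scavenger position on the perpendicular bisector of the primary pair."""
    half = separation / 2.0
    if distance < half:
        raise ValueError(
            f"scavenger_distance {distance} A is closer than the bisector allows "
            f"(>= {half} A for separation {separation} A)"
        )
    h = float(np.sqrt(distance**2 - half**2))
    return np.array([half, 0.0, h])


def make_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Build a synthetic system plus default kinetics for the given recipe."""
    sep = spec.primary_separation
    pos = {1: np.zeros(3), 2: np.array([sep, 0.0, 0.0])}
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "reference_probe":
        hfs = [HyperfineCoupling(1, 0.5, _PROBE_AXIAL_HALF, label="probe-ax-1")]
        if spec.n_probe_nuclei == 2:
            hfs.append(HyperfineCoupling(1, 0.5, 0.3 * _PROTON_LIKE, label="probe-ax-2"))
        init = InitialState("triplet_born")
    elif spec.kind == "flavin_trp_like":
        hfs = [
            HyperfineCoupling(1, 1.0, _N5_LIKE_AXIAL, label="flavin-N5-like"),
            HyperfineCoupling(1, 0.5, _PROTON_LIKE, label="flavin-H-like"),
            HyperfineCoupling(2, 1.0, _TRP_N_LIKE, label="trp-N1-like"),
        ]
        init = InitialState("singlet_born")
    elif spec.kind == "rpm_pair":
        hfs = [HyperfineCoupling(1, 0.5, _PROBE_AXIAL_HALF, label="probe-ax-1")]
        init = InitialState("singlet_born")
    else:  # random_trio
        n_nuc = int(rng.integers(1, 3))
        hfs = []
        for k in range(n_nuc):
            a = rng.normal(0.0, 15.0, size=(3, 3))
            hfs.append(HyperfineCoupling(1, 0.5, 0.5 * (a + a.T), label=f"rand-{k}"))
        init = InitialState("singlet_born")

    if spec.kind == "rpm_pair":
        system = SpinSystemSpec(geometry=TrioGeometry(pos), hyperfines=tuple(hfs))
        k_b = moser_dutton_rate(sep, ETParams(beta=1.4))
        scheme = ReactionScheme(k_f=DEFAULT_K_F, k_b=k_b, kind="RPM")
        return FixtureBundle(system, scheme, init)

    if spec.kind == "random_trio":
        scav = spec.scavenger_distance * _random_unit(rng) + pos[spec.scavenged_site]
    else:
        scav = _bisector_position(sep, spec.scavenger_distance)
    pos[3] = scav
    system = SpinSystemSpec(geometry=TrioGeometry(pos), hyperfines=tuple(hfs))
    r_scav = float(np.linalg.norm(scav - pos[spec.scavenged_site]))
    k_x = moser_dutton_rate(r_scav, ETParams(beta=1.4))
    scheme = ReactionScheme(
        k_f=DEFAULT_K_F, k_x=k_x, scavenged_pair=(spec.scavenged_site, 3), kind="scavenging"
    )
    return FixtureBundle(system, scheme, init)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# geometry + spin config I/O (YAML/JSON-compatible schema, version 1)
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def system_to_dict(system: SpinSystemSpec) -> dict:
    """Canonical plain-dict form of a system (schema version 1)."""
    sites = sorted(system.geometry.positions)
    return {
        "schema_version": SCHEMA_VERSION,
        "sites": [{"label": s, "g": float(system.g.get(s))} for s in sites],
        "positions": {str(s): [float(x) for x in system.geometry.positions[s]] for s in sites},
        "nuclei": [
            {
                "site": hf.host_site,
                "I": float(hf.spin),
                "tensor": [[float(x) for x in row] for row in hf.tensor_mhz],
                "unit": "MHz",
                "label": hf.label,
            }
            for hf in system.hyperfines
        ],
        "J": {f"{a}-{b}": float(v) for (a, b), v in sorted(system.exchange.j_mhz.items())},
        "field": {
            "B0_uT": float(round(system.field_spec.b0 * 1e6, 9)),
            "orientation": [float(x) for x in system.field_spec.orientation],
        },
    }


def _fail(path: str, message: str) -> None:
    raise ValueError(f"config error at {path}: {message}")


def system_from_dict(data: dict) -> SpinSystemSpec:
    """Validate and build a system from the plain-dict schema."""
    if not isinstance(data, dict):
        _fail("$", "expected a mapping")
    if data.get("schema_version") != SCHEMA_VERSION:
        _fail("schema_version", f"expected {SCHEMA_VERSION}, got {data.get('schema_version')!r}")
    sites = data.get("sites")
    if not isinstance(sites, list) or not 2 <= len(sites) <= 3:
        _fail("sites", "expected a list of 2 or 3 site entries")
    g_map, labels = {}, []
    for i, entry in enumerate(sites):
        if not isinstance(entry, dict) or "label" not in entry:
            _fail(f"sites[{i}]", "expected a mapping with a 'label' key")
        labels.append(int(entry["label"]))
        g_map[int(entry["label"])] = float(entry.get("g", G_ELECTRON))
    positions = data.get("positions")
    if not isinstance(positions, dict):
        _fail("positions", "expected a mapping of site label to [x, y, z]")
    pos = {}
    for s in labels:
        raw = positions.get(str(s), positions.get(s))
        if raw is None:
            _fail(f"positions.{s}", "missing position for declared site")
        vec = np.asarray(raw, dtype=float)
        if vec.shape != (3,):
            _fail(f"positions.{s}", f"expected 3 coordinates, got shape {vec.shape}")
        pos[s] = vec
    hfs = []
    for i, entry in enumerate(data.get("nuclei", []) or []):
        path = f"nuclei[{i}]"
        if not isinstance(entry, dict):
            _fail(path, "expected a mapping")
        site = int(entry.get("site", -1))
        if site not in labels:
            _fail(f"{path}.site", f"unknown electron site {site}")
        tensor = np.asarray(entry.get("tensor"), dtype=float)
        if tensor.shape != (3, 3):
            _fail(f"{path}.tensor", f"expected a 3x3 matrix, got shape {tensor.shape}")
        unit = entry.get("unit", "MHz")
        if unit == "mT":
            tensor = tensor * MHZ_PER_MT
        elif unit != "MHz":
            _fail(f"{path}.unit", f"unknown unit {unit!r}; use MHz or mT")
        hfs.append(HyperfineCoupling(site, float(entry.get("I", 0.5)), tensor,
                                     label=str(entry.get("label", ""))))
    j_map = {}
    for key, val in (data.get("J") or {}).items():
        try:
            a, b = (int(x) for x in str(key).split("-"))
        except ValueError:
            _fail(f"J.{key}", "pair key must look like '1-2'")
        j_map[(a, b)] = float(val)
    fdata = data.get("field") or {}
    fs = FieldSpec(
        b0=float(fdata.get("B0_uT", 50.0)) * 1e-6,
        orientation=tuple(fdata.get("orientation", (0.0, 0.0, 1.0))),
    )
    return SpinSystemSpec(
        geometry=TrioGeometry(pos),
        hyperfines=tuple(hfs),
        exchange=ExchangeSpec(j_map),
        g=GTensorSpec(g_map),
        field_spec=fs,
    )


def write_geometry_config(system: SpinSystemSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False)


def read_geometry_config(path) -> SpinSystemSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return system_from_dict(data)


def config_hash(system: SpinSystemSpec) -> str:
    """Stable hash of the canonical config form (provenance stamping)."""
    canonical = yaml.safe_dump(system_to_dict(system), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# PDB convenience: radical-site centroids from residue selections
# ---------------------------------------------------------------------------

def pdb_site_centroids(pdb_path, selectors: list[dict]) -> dict[str, np.ndarray]:
    """Heavy-atom centroids (A) of selected residues in a PDB file.

    Each selector is a mapping with keys ``label``, ``chain``, ``resseq``
    and optionally ``atoms`` (names restricting the selection, e.g. the
    isoalloxazine or indole ring atoms).  Uses the first model and first
    altloc; hydrogens are excluded.  Output preserves selector order.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(pdb_path))
    model = next(structure.get_models())
    out: dict[str, np.ndarray] = {}
    for sel in selectors:
        label = sel["label"]
        chain_id, resseq = sel["chain"], int(sel["resseq"])
        atom_names = set(sel.get("atoms", ()))
        try:
            chain = model[chain_id]
        except KeyError:
            raise KeyError(f"selector {label!r}: chain {chain_id!r} not in structure") from None
        coords = []
        for residue in chain:
            if residue.id[1] != resseq:
                continue
            for atom in residue:
                if atom.element == "H":
                    continue
                if atom_names and atom.get_name() not in atom_names:
                    continue
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]
                coords.append(atom.get_coord())
        if not coords:
            raise KeyError(f"selector {label!r}: no heavy atoms for {chain_id}/{resseq}")
        out[label] = np.mean(np.asarray(coords, dtype=float), axis=0)
    return out
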