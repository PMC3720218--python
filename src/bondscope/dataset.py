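"""Bond-level dataset construction from annotated structure files.

Bonds — not molecules — are the objects the models are trained on.  This
module enumerates non-ring bonds, attaches dissociation-energy labels
(kcal/mol) read from SD-file property fields, removes duplicate bonds
(identical descriptor vectors under a shared reference catalog), and
splits datasets at the molecule level so no molecule contributes bonds to
both partitions.

Annotated SD files store one bond per record: the molecule block is
repeated for each labelled bond, with the label under a configurable
property tag (default ``BDE``) and the bond's 1-based atom numbers under a
second tag (default ``BOND_ATOMS``).  A record with a label but no bond
tag is accepted as a molecule-level annotation.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .descriptors import DescriptorCatalog, compute_vector
from .errors import BondscopeError, CatalogError, LabelingError
from .graph import (
    MolecularGraph,
    atom_type,
    iter_sdf_blocks,
    parse_structure,
    validate_molecule,
)
from .spheres import assign_spheres


@dataclass(frozen=True)
class LabeledBond:
    """A molecule with (optionally) one labelled bond, 0-based atom ids."""

    graph: MolecularGraph
    bond: tuple[int, int] | None
    bde: float | None
    source_index: int = -1


@dataclass
class BondRecord:
    """One dataset row: bond identity, descriptor vector, optional label."""

    mol_id: int | str
    bond: tuple[int, int]
    element_pair: tuple[str, str]
    order: int
    vector: np.ndarray
    bde: float | None = None
    catalog_hash: str = ""
    neighborhood: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.bde is not None and not np.isfinite(self.bde):
            raise LabelingError(f"non-finite label on bond {self.bond} of {self.mol_id}")


@dataclass
class DedupReport:
    """Identical-bond classes found by deduplication."""

    classes: list[list[tuple[int | str, tuple[int, int]]]]

    @property
    def class_sizes(self) -> list[int]:
        return [len(c) for c in self.classes]

    @property
    def n_input(self) -> int:
        return sum(self.class_sizes)

    @property
    def n_unique(self) -> int:
        return len(self.classes)


@dataclass
class DatasetSplit:
    train: list[BondRecord]
    test: list[BondRecord]
    seed: int


def enumerate_bonds(g: MolecularGraph) -> list[tuple[int, int]]:
    """All non-ring covalent bonds, each once, as (i, j) with i < j."""
    return [(b.i, b.j) for b in g.bonds if not b.in_ring]


# ---------------------------------------------------------------------------
# Annotated SDF input / output
# ---------------------------------------------------------------------------


def _split_record(block: str) -> tuple[str, dict[str, str]]:
    """Separate a raw SD record into its molblock and property fields."""
    lines = block.splitlines()
    mol_end = next(
        (k for k, line in enumerate(lines) if line.strip() == "M  END"), None
    )
    if mol_end is None:
        raise LabelingError("record has no 'M  END' line")
    molblock = "\n".join(lines[: mol_end + 1]) + "\n"
    props: dict[str, str] = {}
    k = mol_end + 1
    while k < len(lines):
        line = lines[k].strip()
        if line.startswith(">"):
            tag = line[line.find("<") + 1 : line.rfind(">")]
            values = []
            k += 1
            while k < len(lines) and lines[k].strip() != "":
                values.append(lines[k].strip())
                k += 1
            props[tag] = "\n".join(values)
        k += 1
    return molblock, props


def read_annotated_sdf(
    path,
    property_key: str = "BDE",
    bond_key: str = "BOND_ATOMS",
) -> tuple[list[LabeledBond], list[tuple[int, str]]]:
    """Read a V2000 SDF with per-record BDE annotations.

    Returns ``(labeled, skipped)``; ``skipped`` lists (record index,
    reason) for records that fail parsing or the admission rules
    (net-neutral CHONS).  Records missing ``property_key`` raise a
    :class:`LabelingError` naming every offending record index.
    """
    labeled: list[LabeledBond] = []
    skipped: list[tuple[int, str]] = []
    missing: list[int] = []
    n_records = 0
    for idx, block in enumerate(iter_sdf_blocks(path)):
        n_records += 1
        try:
            molblock, props = _split_record(block)
            graph = parse_structure(molblock)
        except BondscopeError as exc:
            skipped.append((idx, str(exc)))
            continue
        verdict = validate_molecule(graph)
        if not verdict.accepted:
            skipped.append((idx, verdict.reason or "rejected"))
            continue
        if property_key not in props:
            missing.append(idx)
            continue
        try:
            bde = float(props[property_key])
        except ValueError:
            skipped.append((idx, f"unparseable {property_key} value"))
            continue
        bond: tuple[int, int] | None = None
        if bond_key in props:
            i_printed, j_printed = (int(tok) for tok in props[bond_key].split())
            bond = (min(i_printed, j_printed) - 1, max(i_printed, j_printed) - 1)
        labeled.append(LabeledBond(graph, bond, bde, source_index=idx))
    if missing:
        raise LabelingError(
            f"records missing the {property_key!r} property: indices {missing}"
        )
    if n_records == 0:
        warnings.warn(f"{path}: empty SD file", stacklevel=2)
    return labeled, skipped


def write_annotated_sdf(
    entries,
    path,
    property_key: str = "BDE",
    bond_key: str = "BOND_ATOMS",
) -> None:
    """Write labelled bonds as an SDF, one record per bond."""
    writer = Chem.SDWriter(str(path))
    try:
        for entry in entries:
            g = entry.graph
            if g._rdkit is None:
                raise BondscopeError("graph carries no structure record")
            mol = Chem.Mol(g._rdkit)
            if entry.bde is not None:
                mol.SetProp(property_key, f"{entry.bde:.6f}")
            if entry.bond is not None:
                mol.SetProp(bond_key, f"{entry.bond[0] + 1} {entry.bond[1] + 1}")
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Record construction
# ---------------------------------------------------------------------------


def _make_record(
    g: MolecularGraph,
    bond: tuple[int, int],
    catalog: DescriptorCatalog,
    mol_id,
    bde=None,
) -> BondRecord:
    i, j = min(bond), max(bond)
    b = g.bond_between(i, j)
    if b is None:
        raise LabelingError(f"molecule {mol_id}: no bond between atoms {i} and {j}")
    env = assign_spheres(g, (i, j))
    neighborhood = tuple(
        sorted(
            atom_type(g, a, "cn")
            for a in range(g.n_atoms)
            if env.spheres[a] == 1
        )
    )
    return BondRecord(
        mol_id=mol_id,
        bond=(i, j),
        element_pair=tuple(sorted((g.elements[i], g.elements[j]))),
        order=b.order,
        vector=compute_vector(g, (i, j), catalog),
        bde=bde,
        catalog_hash=catalog.content_hash(),
        neighborhood=neighborhood,
    )


def build_records(
    labeled: list[LabeledBond],
    catalog: DescriptorCatalog,
    mol_ids: list | None = None,
) -> list[BondRecord]:
    """Bond records for labelled bonds; entries without a bond raise."""
    records = []
    for k, entry in enumerate(labeled):
        if entry.bond is None:
            raise LabelingError(
                f"entry {k} carries no bond; cannot build a bond record"
            )
        if mol_ids is not None:
            mol_id = mol_ids[k]
        elif entry.graph.title:
            mol_id = entry.graph.title
        else:
            mol_id = entry.source_index if entry.source_index >= 0 else k
        records.append(
            _make_record(entry.graph, entry.bond, catalog, mol_id, entry.bde)
        )
    return records


def records_from_molecules(
    graphs: list[MolecularGraph],
    catalog: DescriptorCatalog,
    mol_ids: list | None = None,
) -> list[BondRecord]:
    """Unlabelled records for every non-ring bond of every molecule."""
    records = []
    for k, g in enumerate(graphs):
        mol_id = mol_ids[k] if mol_ids is not None else k
        for bond in enumerate_bonds(g):
            records.append(_make_record(g, bond, catalog, mol_id))
    return records


# ---------------------------------------------------------------------------
# Deduplication, splitting, sampling
# ---------------------------------------------------------------------------


def deduplicate(records: list[BondRecord]) -> tuple[list[BondRecord], DedupReport]:
    """Keep one representative per identical-descriptor-vector class.

    Bond identity is equality of the full descriptor vector under the
    shared reference catalog; mixing records computed under different
    catalogs raises :class:`CatalogError`.  Idempotent: applying it to its
    own output changes nothing.
    """
    hashes = {r.catalog_hash for r in records}
    if len(hashes) > 1:
        raise CatalogError(f"records mix descriptor catalogs: {sorted(hashes)}")
    unique: list[BondRecord] = []
    classes: dict[bytes, list[tuple]] = {}
    order: list[bytes] = []
    for r in records:
        key = np.ascontiguousarray(r.vector).tobytes()
        if key not in classes:
            classes[key] = []
            order.append(key)
            unique.append(r)
        classes[key].append((r.mol_id, r.bond))
    report = DedupReport(classes=[classes[k] for k in order])
    return unique, report


def split_by_molecule(
    records: list[BondRecord], fraction: float, seed: int
) -> DatasetSplit:
    """Seeded molecule-level partition: every molecule's bonds land on one
    side only."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    mol_ids = sorted({r.mol_id for r in records}, key=str)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(mol_ids))
    n_train = int(round(fraction * len(mol_ids)))
    n_train = max(1, min(n_train, len(mol_ids) - 1)) if len(mol_ids) > 1 else 1
    train_ids = {mol_ids[p] for p in perm[:n_train]}
    train = [r for r in records if r.mol_id in train_ids]
    test = [r for r in records if r.mol_id not in train_ids]
    return DatasetSplit(train=train, test=test, seed=seed)


def stratified_sample(
    records: list[BondRecord], per_class: int, seed: int
) -> list[BondRecord]:
    """At most ``per_class`` records per (element pair, bond order,
    sphere-1 neighbour types) stratum; plumbing for balancing synthetic
    corpora in place of database enrichment."""
    rng = np.random.default_rng(seed)
    buckets: dict[tuple, list[BondRecord]] = defaultdict(list)
    for r in records:
        buckets[(r.element_pair, r.order, r.neighborhood)].append(r)
    sample: list[BondRecord] = []
    for key in sorted(buckets, key=str):
        group = buckets[key]
        if len(group) <= per_class:
            sample.extend(group)
        else:
            picks = rng.choice(len(group), size=per_class, replace=False)
            sample.extend(group[p] for p in sorted(picks))
    return sample


# ---------------------------------------------------------------------------
# Matrices and summaries
# ---------------------------------------------------------------------------


def design_matrix(records: list[BondRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into (X, y); y entries are NaN for unlabelled bonds."""
    X = np.vstack([r.vector for r in records])
    y = np.array([np.nan if r.bde is None else r.bde for r in records])
    return X, y


def to_frame(records: list[BondRecord], catalog: DescriptorCatalog) -> pd.DataFrame:
    """Records as a table with named descriptor columns (the TSV layout)."""
    X, y = design_matrix(records)
    frame = pd.DataFrame(X, columns=catalog.names)
    frame.insert(0, "mol_id", [r.mol_id for r in records])
    frame.insert(1, "bond", [f"{r.bond[0]}-{r.bond[1]}" for r in records])
    frame.insert(2, "element_pair", ["-".join(r.element_pair) for r in records])
    frame.insert(3, "order", [r.order for r in records])
    frame.insert(4, "bde", y)
    return frame


def write_descriptor_table(records, catalog, path) -> None:
    to_frame(records, catalog).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LabelStatistics:
    """Summary statistics of a labelled bond set (kcal/mol)."""

    n_bonds: int
    max_bde: float
    min_bde: float
    min_positive_bde: float
    n_negative: int
    class_means: dict[tuple[tuple[str, str], int], float]


def label_statistics(records: list[BondRecord]) -> LabelStatistics:
    """Training-set label summary: extremes, negative-label count, and the
    per-(element pair, bond order) means that the fixed-value baseline
    uses."""
    labelled = [r for r in records if r.bde is not None]
    if not labelled:
        raise LabelingError("no labelled records")
    values = np.array([r.bde for r in labelled])
    positive = values[values > 0]
    sums: dict[tuple, list[float]] = defaultdict(list)
    for r in labelled:
        sums[(r.element_pair, r.order)].append(r.bde)
    return LabelStatistics(
        n_bonds=len(labelled),
        max_bde=float(values.max()),
        min_bde=float(values.min()),
        min_positive_bde=float(positive.min()) if positive.size else float("nan"),
        n_negative=int((values < 0).sum()),
        class_means={k: float(np.mean(v)) for k, v in sums.items()},
    )
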