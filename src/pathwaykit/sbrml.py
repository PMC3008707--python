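"""Results dialect: quantitative tables bound to model entities.

Implements a documented, versioned subset of an SBRML-like results format:
one operation per document and a single two-dimensional result component
(time x entity).  This is exactly the shape exchanged between simulation
output and calibration input.  Columns bind either to a model entity id or
to a MIRIAM URI, which can later be resolved against a reference model via
its annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lxml import etree

from .model import Model

__all__ = ["ResultSet", "ColumnBinding", "write_sbrml", "read_sbrml",
           "table_to_sbrml", "SbrmlError", "timecourse_to_resultset"]

NSMAP = {None: "https://pathwaykit.dev/sbrml-subset/1"}
NS = "{https://pathwaykit.dev/sbrml-subset/1}"


class SbrmlError(ValueError):
    """Schema violation; the message carries the document location."""


@dataclass(frozen=True)
class ColumnBinding:
    column: str  # column label in the source table
    entity: str  # model entity id or MIRIAM URI

    @property
    def is_uri(self) -> bool:
        return self.entity.startswith(("http://", "https://", "urn:"))


@dataclass
class ResultSet:
    model_ref: str
    operation: str = "simulation"  # simulation | experiment
    method: str = ""
    model_checksum: Optional[str] = None
    columns: list[ColumnBinding] = field(default_factory=list)
    times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    values: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            self.values = self.values.reshape(len(self.times), len(self.columns))
        if self.values.shape != (len(self.times), len(self.columns)):
            raise SbrmlError(
                f"table shape {self.values.shape} does not match "
                f"{len(self.times)} time points x {len(self.columns)} columns")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise SbrmlError("time column is not strictly increasing")

    def column_values(self, column: str) -> np.ndarray:
        for i, cb in enumerate(self.columns):
            if cb.column == column:
                return self.values[:, i]
        raise KeyError(column)

    def resolve(self, model: Model) -> dict[str, str]:
        """Map each column to a species id of *model*.

        Entity ids must exist in the model; URIs resolve via annotation
        lookup.  Raises :class:`SbrmlError` listing unresolvable columns.
        """
        out: dict[str, str] = {}
        uri_index: dict[str, str] = {}
        for sp in model.species:
            for a in sp.annotations:
                uri_index.setdefault(a.resource_uri, sp.id)
        bad: list[str] = []
        for cb in self.columns:
            if cb.is_uri:
                sid = uri_index.get(cb.entity)
            else:
                sid = cb.entity if cb.entity in model.species_ids() else None
            if sid is None:
                bad.append(cb.column)
            else:
                out[cb.column] = sid
        if bad:
            raise SbrmlError(f"columns do not resolve against model "
                             f"{model.id!r}: {bad}")
        return out


def write_sbrml(rs: ResultSet) -> str:
    """Serialise a result set to the XML dialect."""
    root = etree.Element(f"{NS}sbrml", nsmap=NSMAP, version="1")
    model_el = etree.SubElement(root, f"{NS}model", ref=rs.model_ref)
    if rs.model_checksum:
        model_el.set("checksum", rs.model_checksum)
    etree.SubElement(root, f"{NS}operation", kind=rs.operation,
                     method=rs.method)
    result = etree.SubElement(root, f"{NS}result")
    cols = etree.SubElement(result, f"{NS}columns")
    for cb in rs.columns:
        etree.SubElement(cols, f"{NS}column", label=cb.column,
                         entity=cb.entity)
    rows = etree.SubElement(result, f"{NS}rows")
    for i, t in enumerate(rs.times):
        row = etree.SubElement(rows, f"{NS}row", time=repr(float(t)))
        row.text = " ".join(repr(float(v)) for v in rs.values[i])
    return etree.tostring(root, pretty_print=True, encoding="unicode",
                          xml_declaration=False)


def read_sbrml(text: str) -> ResultSet:
    """Parse the XML dialect; schema violations name their location."""
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as e:
        raise SbrmlError(f"not well-formed XML: {e}") from None
    if root.tag != f"{NS}sbrml":
        raise SbrmlError(f"unexpected root element {root.tag!r}")
    model_el = root.find(f"{NS}model")
    op_el = root.find(f"{NS}operation")
    result = root.find(f"{NS}result")
    if model_el is None or op_el is None or result is None:
        raise SbrmlError("missing model/operation/result element")
    columns = [
        ColumnBinding(c.get("label"), c.get("entity"))
        for c in result.find(f"{NS}columns")
    ]
    times, values = [], []
    for row in result.find(f"{NS}rows"):
        try:
            times.append(float(row.get("time")))
        except (TypeError, ValueError):
            raise SbrmlError(
                f"bad time attribute at line {row.sourceline}") from None
        cells = (row.text or "").split()
        if len(cells) != len(columns):
            raise SbrmlError(
                f"row at line {row.sourceline}: {len(cells)} cells for "
                f"{len(columns)} columns")
        values.append([float(c) for c in cells])
    return ResultSet(
        model_ref=model_el.get("ref"),
        model_checksum=model_el.get("checksum"),
        operation=op_el.get("kind"),
        method=op_el.get("method") or "",
        columns=columns,
        times=np.array(times),
        values=np.array(values).reshape(len(times), len(columns)),
    )


def table_to_sbrml(
    rows: Sequence[dict],
    model: Model,
    time_key: str = "time",
    operation: str = "experiment",
    method: str = "",
) -> tuple[ResultSet, list[str]]:
    """Bind a tabular dataset (list of row dicts) against a model.

    Non-time columns are identified by model species id, annotation
    accession, or full URI.  Returns the result set plus the headers that
    could not be resolved (excluded from the output, reported).
    """
    headers = [k for k in (rows[0].keys() if rows else []) if k != time_key]
    acc_index: dict[str, str] = {}
    for sp in model.species:
        for a in sp.annotations:
            acc_index.setdefault(a.accession, sp.id)
            acc_index.setdefault(a.resource_uri, sp.id)
    sids = model.species_ids()
    bound, unresolved = [], []
    for h in headers:
        if h in sids:
            bound.append(ColumnBinding(h, h))
        elif h in acc_index:
            bound.append(ColumnBinding(h, acc_index[h]))
        else:
            unresolved.append(h)
    times = [float(r[time_key]) for r in rows]
    values = [[float(r[cb.column]) for cb in bound] for r in rows]
    rs = ResultSet(model_ref=model.id, operation=operation, method=method,
                   columns=bound, times=np.array(times),
                   values=np.array(values).reshape(len(times), len(bound)))
    return rs, unresolved


def timecourse_to_resultset(tc, model_ref: Optional[str] = None,
                            method: str = "ode-timecourse") -> ResultSet:
    """Wrap a simulated :class:`~pathwaykit.ode.TimeCourse` as a result set."""
    return ResultSet(
        model_ref=model_ref or tc.provenance.get("model_id", "model"),
        operation="simulation",
        method=method,
        columns=[ColumnBinding(sid, sid) for sid in tc.species_ids],
        times=tc.times,
        values=tc.values,
    )
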