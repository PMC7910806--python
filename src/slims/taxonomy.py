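"""Master taxonomy: accepted names, synonyms, families, and name resolution.

The project maintains one internal taxonomic resource (family, accepted
binomial, synonyms, taxon identifier). Herbarium determinations vary in
author citation and infraspecific formatting, so matching uses the
lower-cased binomial: genus plus specific epithet, with author strings and
infraspecific ranks stripped. Names resolving to several accepted taxa are
queued for human review rather than auto-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REQUIRED_COLUMNS = ("family", "scientific_name", "synonyms", "taxon_id")
SYNONYM_SEP = "|"

_RANK_TOKENS = {"var", "var.", "subsp", "subsp.", "ssp", "ssp.", "f", "f.",
                "forma", "cv", "cv."}


def normalize_name(name: str) -> str | None:
    """Canonical lower-cased binomial, or None when no epithet is present.

    "Quercus alba L." -> "quercus alba"; "Quercus alba var. repanda" ->
    "quercus alba"; "Quercus L." -> None (genus only).
    """
    if not name or not name.strip():
        return None
    tokens = name.replace("×", " ").split()
    if not tokens:
        return None
    genus = tokens[0]
    if not genus[0].isalpha():
        return None
    epithet = None
    if len(tokens) > 1:
        t = tokens[1]
        # A capitalised mixed-case token ("Siebold") is an author citation;
        # lower-case or all-caps tokens are epithets however they were typed.
        if (t.lower() not in _RANK_TOKENS and "." not in t
                and (t[0].islower() or t.isupper())):
            epithet = t
    if epithet is None:
        return None
    return f"{genus.lower()} {epithet.lower()}"


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: str
    family: str
    accepted_name: str
    synonyms: tuple[str, ...] = ()

    @property
    def genus(self) -> str:
        return self.accepted_name.split()[0]


@dataclass(frozen=True)
class NameResolution:
    query: str
    status: str  # accepted | synonym | ambiguous | unknown
    taxon_id: str | None = None
    candidates: tuple[str, ...] = ()


@dataclass
class Taxonomy:
    records: dict[str, TaxonRecord] = field(default_factory=dict)
    _accepted_index: dict[str, str] = field(default_factory=dict)
    _synonym_index: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Taxonomy":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"taxonomy table missing columns: {missing}")
        tax = cls()
        dup_names: list[str] = []
        for row in df.itertuples(index=False):
            name = str(row.scientific_name).strip()
            key = normalize_name(name)
            if key is None:
                raise ValueError(f"unusable accepted name: {name!r}")
            if key in tax._accepted_index:
                dup_names.append(name)
                continue
            syn_raw = "" if pd.isna(row.synonyms) else str(row.synonyms)
            synonyms = tuple(
                s.strip() for s in syn_raw.split(SYNONYM_SEP) if s.strip())
            rec = TaxonRecord(str(row.taxon_id), str(row.family).strip(),
                              name, synonyms)
            if rec.taxon_id in tax.records:
                raise ValueError(f"duplicate taxon_id: {rec.taxon_id}")
            tax.records[rec.taxon_id] = rec
            tax._accepted_index[key] = rec.taxon_id
            for syn in synonyms:
                skey = normalize_name(syn)
                if skey is not None:
                    tax._synonym_index.setdefault(skey, []).append(rec.taxon_id)
        if dup_names:
            raise ValueError(f"duplicate accepted names: {sorted(dup_names)}")
        return tax

    @classmethod
    def from_csv(cls, path) -> "Taxonomy":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def resolve(self, query: str) -> NameResolution:
        """Resolve a determination to a taxon.

        Exact accepted-name match wins over a synonym match; a synonym
        shared by several accepted names is ambiguous. Pure function of
        (taxonomy, query).
        """
        key = normalize_name(query or "")
        if key is None:
            return NameResolution(query, "unknown")
        tid = self._accepted_index.get(key)
        if tid is not None:
            return NameResolution(query, "accepted", taxon_id=tid)
        hits = sorted(set(self._synonym_index.get(key, ())))
        if len(hits) == 1:
            return NameResolution(query, "synonym", taxon_id=hits[0])
        if len(hits) >= 2:
            return NameResolution(query, "ambiguous", candidates=tuple(hits))
        return NameResolution(query, "unknown")

    def family_of(self, taxon_id: str) -> str:
        return self.records[taxon_id].family

    def genus_of(self, taxon_id: str) -> str:
        return self.records[taxon_id].genus

    def species_per_genus(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records.values():
            counts[rec.genus] = counts.get(rec.genus, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"family": r.family, "scientific_name": r.accepted_name,
             "synonyms": SYNONYM_SEP.join(r.synonyms), "taxon_id": r.taxon_id}
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def link_sample(db, taxonomy: Taxonomy, sample_uuid: str,
                query: str) -> NameResolution:
    """Link a sample UUID to the taxon its determination resolves to.

    Unambiguous resolutions write one link row (idempotent for repeats of
    the same taxon). Ambiguous or unknown names, and attempts to link one
    UUID to a second taxon, queue a violation for human review instead of
    writing a link.
    """
    from .datastore import AuditViolation

    res = taxonomy.resolve(query)
    if res.status in ("accepted", "synonym"):
        prior = db.conn.execute(
            "SELECT taxon_id FROM taxon_sample_links WHERE sample_uuid = ?",
            (sample_uuid,)).fetchone()
        if prior is None:
            db.conn.execute(
                "INSERT INTO taxon_sample_links (taxon_id, sample_uuid)"
                " VALUES (?, ?)", (res.taxon_id, sample_uuid))
        elif prior["taxon_id"] != res.taxon_id:
            db.add_violation(AuditViolation(
                "multi_taxon_mapping", sample_uuid,
                f"already linked to {prior['taxon_id']}, determination"
                f" {query!r} resolves to {res.taxon_id}",
                "taxon_sample_links"))
    elif res.status == "ambiguous":
        db.add_violation(AuditViolation(
            "multi_taxon_mapping", sample_uuid,
            f"name {query!r} matches taxa {', '.join(res.candidates)}",
            "sampling"))
    else:
        db.add_violation(AuditViolation(
            "orphan_reference", sample_uuid,
            f"unknown taxon name {query!r}", "sampling"))
    return res
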