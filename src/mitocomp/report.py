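"""Report rendering: rounded tabular views over full-precision results.

All computation modules emit full precision; rounding conventions (A+T% to
one decimal, skews to two, distances to five) live here only, so published-
table-style equality checks are well defined and every rendered number can
be re-derived from the JSON full-precision export.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import pandas as pd

from . import codon as codonmod
from . import composition as comp
from .io import Mitogenome

AT_DECIMALS = 1
SKEW_DECIMALS = 2
DIST_DECIMALS = 5

_PARTITION_ORDER = ("Mito", "PCGs", "rRNAs", "tRNAs", "D-loop")


def _r(value, decimals):
    return None if value is None else round(value, decimals)


def partition_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """Rows = genomes, columns = partition x {A+T%, AT-skew, GC-skew},
    rounded as conventionally printed; missing partitions render as NA."""
    rows = []
    for g in genomes:
        recs = {r.region_label: r for r in comp.partition_stats(g)}
        row: dict = {"accession": g.accession, "organism": g.organism}
        for part in _PARTITION_ORDER:
            r = recs.get(part)
            row[f"{part}:A+T%"] = _r(r.at_percent, AT_DECIMALS) if r else None
            row[f"{part}:AT-skew"] = _r(r.at_skew, SKEW_DECIMALS) if r else None
            row[f"{part}:GC-skew"] = _r(r.gc_skew, SKEW_DECIMALS) if r else None
        rows.append(row)
    return pd.DataFrame(rows)


def codon_position_table(g: Mitogenome) -> pd.DataFrame:
    """Base percentages by partition and codon position, one genome."""
    from .io import extract_gene_sequence

    cds = [extract_gene_sequence(g, f) for f in g.features_of_type("CDS")]
    rows = []
    if cds:
        cpc = comp.codon_position_composition(cds)
        label = {"pooled": "Proteins", "1": "1st", "2": "2nd", "3": "3rd"}
        for key in ("pooled", "1", "2", "3"):
            if key in cpc.positions:
                rows.append({"partition": label[key],
                             **{b: round(v, AT_DECIMALS)
                                for b, v in cpc.positions[key].items()}})
    for types, label in ((("tRNA",), "tRNAs"), (("rRNA",), "rRNAs")):
        seq = "".join(
            comp._majority_slice(g, f) for f in g.features_of_type(*types)
        )
        if seq:
            rec = comp.composition_record(label, seq)
            rows.append({"partition": label,
                         **{b: round(v, AT_DECIMALS)
                            for b, v in rec.base_percents.items()}})
    return pd.DataFrame(rows)


def per_gene_table(g: Mitogenome) -> pd.DataFrame:
    df = comp.per_gene_profile(g)
    df["at_percent"] = df["at_percent"].round(AT_DECIMALS)
    df["at_skew"] = df["at_skew"].round(SKEW_DECIMALS)
    df["gc_skew"] = df["gc_skew"].round(SKEW_DECIMALS)
    return df


def rscu_report(genomes: list[Mitogenome], include_stops: bool = True
                ) -> pd.DataFrame:
    """Pooled codon/RSCU long table over concatenated PCGs of all genomes."""
    from .io import extract_gene_sequence

    cds = [extract_gene_sequence(g, f)
           for g in genomes for f in g.features_of_type("CDS")]
    table = codonmod.codon_counts(cds, include_stops=include_stops)
    df = codonmod.rscu_table(table)
    df["rscu"] = df["rscu"].round(3)
    return df


def distance_long_table(long: pd.DataFrame) -> pd.DataFrame:
    out = long.copy()
    for col in ("P", "Q", "p_dist", "k2p"):
        out[col] = out[col].round(DIST_DECIMALS)
    return out


def full_precision_json(obj, path) -> None:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"unserializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default, allow_nan=True)
        fh.write("\n")


def manifest(inputs: list, params: dict) -> dict:
    """Reproducibility manifest: package version, parameters, input digests."""
    from . import __version__

    digests = {}
    for p in inputs:
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        digests[str(p)] = h.hexdigest()
    return {"version": __version__, "parameters": params, "inputs": digests}
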