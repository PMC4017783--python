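"""Plain-text readers and writers for the pipeline's file formats.

* Genotype TSV — header of locus IDs, one row per individual, cells
  ``total_cn:allele1_count`` (e.g. ``2:1``).
* Haplotype TSV — one header row, then two rows per individual (same ID)
  holding per-locus chromosome symbols from ``{-, 0, 1, 00, 01, 11}``.
  Used for both truth and phased output; phased files start with ``#``
  comment lines recording mode, K, seed and block size.
* Frequency TSV — ``haplotype<TAB>frequency`` with the haplotype written
  as comma-joined symbols.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .model import (
    Assignment,
    GenotypeError,
    GenotypeSet,
    GenotypeVector,
    Haplotype,
    NON_INTERNAL,
    SiteObservation,
)


def _locus_header(L: int) -> list[str]:
    return [f"locus{j:04d}" for j in range(L)]


def write_genotypes(genotypes: GenotypeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(_locus_header(genotypes.n_loci)) + "\n")
        for g in genotypes:
            cells = [str(obs) for obs in g.sites]
            fh.write(g.individual_id + "\t" + "\t".join(cells) + "\n")


def read_genotypes(path: str | Path) -> GenotypeSet:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise GenotypeError(f"{path}: empty genotype file")
        n_loci = len(header.rstrip("\n").split("\t")) - 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_loci + 1:
                raise GenotypeError(
                    f"{path}:{lineno}: expected {n_loci + 1} columns, "
                    f"got {len(fields)}"
                )
            sites = []
            for col, cell in enumerate(fields[1:], start=2):
                try:
                    cn_s, cnt_s = cell.split(":")
                    obs = SiteObservation(int(cn_s), int(cnt_s))
                except (ValueError, GenotypeError) as exc:
                    raise GenotypeError(
                        f"{path}:{lineno} column {col}: bad cell {cell!r} ({exc})"
                    ) from exc
                sites.append(obs)
            rows.append(GenotypeVector(fields[0], tuple(sites)))
    return GenotypeSet(tuple(rows))


def write_haplotypes(
    ids: Sequence[str],
    assignments: Sequence[Assignment],
    path: str | Path,
    header_meta: Mapping[str, object] | None = None,
) -> None:
    if len(ids) != len(assignments):
        raise ValueError("ids and assignments must align")
    with open(path, "w") as fh:
        if header_meta:
            for k, v in header_meta.items():
                fh.write(f"# {k}={v}\n")
        L = len(assignments[0].haplotypes[0]) if assignments else 0
        fh.write("individual\t" + "\t".join(_locus_header(L)) + "\n")
        for ind, a in zip(ids, assignments):
            for h in a.haplotypes:
                fh.write(ind + "\t" + "\t".join(h.states) + "\n")


def read_haplotypes(path: str | Path) -> tuple[list[str], list[Assignment]]:
    """Read a haplotype TSV back into per-individual diplotype assignments."""
    ids: list[str] = []
    rows: dict[str, list[Haplotype]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "individual":
                continue
            hap = Haplotype(NON_INTERNAL, tuple(fields[1:]))
            if fields[0] not in rows:
                ids.append(fields[0])
                rows[fields[0]] = []
            rows[fields[0]].append(hap)
    assignments = []
    for ind in ids:
        haps = rows[ind]
        if len(haps) != 2:
            raise GenotypeError(
                f"{path}: individual {ind} has {len(haps)} haplotype rows, expected 2"
            )
        assignments.append(Assignment(tuple(haps)))
    return ids, assignments


def write_frequencies(freqs: Mapping[Haplotype, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\tfrequency\n")
        for h, f in sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(",".join(h.states) + f"\t{f:.10g}\n")


def read_frequencies(path: str | Path) -> dict[Haplotype, float]:
    out: dict[Haplotype, float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "haplotype")) or not line.strip():
                continue
            hap_s, freq_s = line.rstrip("\n").split("\t")
            out[Haplotype(NON_INTERNAL, tuple(hap_s.split(",")))] = float(freq_s)
    return out
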