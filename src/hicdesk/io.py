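"""Simple-table readers and writers.

All on-disk tables are plain TSV with ``#`` provenance headers.
Fragment tables are written 1-based inclusive (the common convention for
deliverable tables); everything is converted back to 0-based half-open
on reading.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .genome_model import FragmentSet, GenomeIndex, HicdeskError


def provenance_header(command: str, **params) -> str:
    parts = [f"hicdesk {__version__}", command]
    parts += [f"{k}={v}" for k, v in params.items() if v is not None]
    return " ".join(parts)


def write_fragment_table(path: str, fragments: FragmentSet, header: str = "") -> None:
    """Fragment table: fragmentID, chromosome, start (1-based), end (inclusive), length."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f"# mode={fragments.mode} provenance={fragments.provenance}\n")
        fh.write("# genome=" + ",".join(
            f"{n}:{fragments.genome.lengths[n]}" for n in fragments.genome.names
        ) + "\n")
        fh.write("fragmentID\tchromosome\tstart\tend\tlength\n")
        for f in fragments:
            fh.write(f"{f.id}\t{f.chrom}\t{f.start + 1}\t{f.end}\t{f.length}\n")


def read_fragment_table(path: str) -> FragmentSet:
    mode, prov, genome = "binned", "", None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# mode="):
                fields = line[2:].strip().split(" ", 1)
                mode = fields[0].split("=", 1)[1]
                prov = fields[1].split("=", 1)[1] if len(fields) > 1 else ""
            elif line.startswith("# genome="):
                items = line.split("=", 1)[1].strip().split(",")
                names = [i.rsplit(":", 1)[0] for i in items]
                lengths = [int(i.rsplit(":", 1)[1]) for i in items]
                genome = GenomeIndex(names, lengths)
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    if genome is None:
        ends = df.groupby("chromosome", sort=False)["end"].max()
        genome = GenomeIndex(list(ends.index), list(ends.values))
    code = {n: i for i, n in enumerate(genome.names)}
    codes = df["chromosome"].map(code).to_numpy()
    order = np.lexsort((df["start"].to_numpy(), codes))
    return FragmentSet(
        genome,
        codes[order],
        df["start"].to_numpy()[order] - 1,
        df["end"].to_numpy()[order],
        mode,
        prov,
    )
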