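#!/usr/bin/env python
"""QC-filter and log-normalize the simulated single-cell matrix.

Cells with <200 detected genes, >5000 detected genes, or >20% mitochondrial
reads are excluded (strict inequalities); survivors are depth-normalized to
10,000 counts and ln(1+x) transformed.  Writes the filtered matrix and the
QC report under results/.
"""

import argparse
from pathlib import Path

import metasig as ms
import metasig.io as msio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    m, ann = msio.read_counts(args.indir / "sc_counts")
    filtered, ann2, report = ms.qc_filter(m, ms.QCConfig(), ann)
    msio.write_counts(filtered, args.outdir / "sc_counts_qc", annotation=ann2)
    msio.write_json(report.to_dict(), args.outdir / "qc_report.json")
    print(f"QC: {report.n_input_cells} cells in, {report.n_retained} retained "
          f"({report.n_removed_low_genes} low-gene, "
          f"{report.n_removed_high_genes} high-gene, "
          f"{report.n_removed_mito} high-mito removed); "
          f"median {report.median_genes_per_cell:.0f} genes/cell")


if __name__ == "__main__":
    main()
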