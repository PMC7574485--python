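"""One-off generator for the bundled amino-acid dissimilarity tables.

Regenerates src/divergc/data/{sneath,epstein}.tsv from the attribute table
and polarity/size formula in divergc._matrices.  Run from the repo root:

    python scripts/derive_matrices.py
"""

import importlib.util
from pathlib import Path

# load the derivation module by path: the package itself expects the data
# files this script writes, so a plain package import would be circular
_src = Path(__file__).resolve().parent.parent / "src" / "divergc" / "_matrices.py"
_spec = importlib.util.spec_from_file_location("_matrices", _src)
_matrices = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_matrices)
format_matrix_tsv = _matrices.format_matrix_tsv


def main() -> None:
    outdir = Path(__file__).resolve().parent.parent / "src" / "divergc" / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("sneath", "epstein"):
        path = outdir / f"{name}.tsv"
        path.write_text(format_matrix_tsv(name))
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
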