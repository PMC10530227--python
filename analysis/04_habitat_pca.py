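"""Step I: correlation-matrix PCA of the presence cells.

Standardizes the 13 variables by the presence means/s.d. (equal weight
per variable), eigendecomposes the correlation matrix, and reports the
explained variance, variable contributions and cos^2 on the leading
axes.  The presence space defined here is the frame into which absence
cells are projected in step III.
"""

import pandas as pd

from common import FEATURES_CSV, RESULTS, SCRATCH, ensure_dirs
from icehab import fit_pca
from icehab.features import FEATURE_COLUMNS
from icehab.figures import plot_correlation_circle

ensure_dirs()
table = pd.read_csv(FEATURES_CSV)
presence = table[table["is_presence"]]

space = fit_pca(presence, FEATURE_COLUMNS, q=4)

axes = [f"PC{i+1}" for i in range(space.p)]
pd.DataFrame(
    {"eigenvalue": space.eigenvalues, "explained_pct": space.explained_pct},
    index=axes,
).round(4).to_csv(RESULTS / "pca_eigenvalues.csv")
space.loadings_frame().round(4).to_csv(RESULTS / "pca_loadings.csv")
pd.DataFrame(space.contributions, index=FEATURE_COLUMNS, columns=axes).round(2).to_csv(
    RESULTS / "pca_contributions.csv"
)
pd.DataFrame(space.cos2, index=FEATURE_COLUMNS, columns=axes).round(3).to_csv(
    RESULTS / "pca_cos2.csv"
)

cum = space.explained_pct.cumsum()
print(f"PCA on {len(presence)} presence cells, {space.p} variables")
for i in range(4):
    top = pd.Series(space.contributions[:, i], index=FEATURE_COLUMNS).nlargest(2)
    tops = ", ".join(f"{v} ({c:.0f}%)" for v, c in top.items())
    print(f"  PC{i+1}: {space.explained_pct[i]:5.1f}% of variance — top contributions: {tops}")
print(f"  Q=4 axes retain {cum[3]:.1f}% of total variance")
fig_dir = SCRATCH / "figures"
fig_dir.mkdir(exist_ok=True)
plot_correlation_circle(space, fig_dir / "correlation_circle.png")
print("wrote pca_eigenvalues.csv, pca_loadings.csv, pca_contributions.csv, pca_cos2.csv")
print(f"figure: {fig_dir / 'correlation_circle.png'}")
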