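"""Generate the correlated-AUC r-table by bivariate binormal simulation.

For each (underlying score correlation rho, common AUC A): simulate paired
scores for both classes, compute the two AUC estimates per replicate, and
record (i) the mean of the average class-conditional Spearman correlation
(the table's row coordinate) and (ii) the Pearson correlation between the
two AUC estimates across replicates (the table entry).
"""
import numpy as np
from scipy.stats import norm, rankdata

rng = np.random.default_rng(1983)
rhos = np.arange(0.0, 0.91, 0.1)
aucs = np.array([0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.975])
reps, n = 4000, 100

def spearman_rows(x, y):
    rx = rankdata(x, axis=1); ry = rankdata(y, axis=1)
    rx = (rx - rx.mean(1, keepdims=True)) / rx.std(1, keepdims=True)
    ry = (ry - ry.mean(1, keepdims=True)) / ry.std(1, keepdims=True)
    return (rx * ry).mean(1)

def auc_rows(pos, neg):
    allv = np.concatenate([pos, neg], axis=1)
    r = rankdata(allv, axis=1)
    u = r[:, :n].sum(1) - n * (n + 1) / 2
    return u / (n * n)

row_coord = np.zeros((len(rhos), len(aucs)))
r_auc = np.zeros_like(row_coord)
for i, rho in enumerate(rhos):
    L = np.linalg.cholesky(np.array([[1, rho], [rho, 1]]))
    for j, A in enumerate(aucs):
        d = np.sqrt(2) * norm.ppf(A)
        zp = rng.standard_normal((reps, n, 2)) @ L.T + d
        zn = rng.standard_normal((reps, n, 2)) @ L.T
        ax = auc_rows(zp[:, :, 0], zn[:, :, 0])
        ay = auc_rows(zp[:, :, 1], zn[:, :, 1])
        ravg = 0.5 * (spearman_rows(zp[:, :, 0], zp[:, :, 1])
                      + spearman_rows(zn[:, :, 0], zn[:, :, 1]))
        row_coord[i, j] = ravg.mean()
        r_auc[i, j] = np.corrcoef(ax, ay)[0, 1]
np.set_printoptions(precision=4, suppress=True)
print("row_coord ="); print(repr(np.round(row_coord, 4).tolist()))
print("r_auc ="); print(repr(np.round(r_auc, 4).tolist()))
print("aucs ="); print(repr(aucs.tolist()))
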