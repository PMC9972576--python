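# Regenerates limma_fixture_expected.csv from the frozen y/design CSVs.
# Run from the repo root:  Rscript tests/data/make_limma_fixture.R
suppressMessages(library(limma))
y <- as.matrix(read.csv("tests/data/limma_fixture_y.csv", row.names = 1))
X <- as.matrix(read.csv("tests/data/limma_fixture_design.csv", row.names = 1))
fit <- lmFit(y, X)
fit <- eBayes(fit)
out <- data.frame(
  probe_id = rownames(y),
  coef_group = fit$coefficients[, "group"],
  s2 = fit$sigma^2,
  s2_post = fit$s2.post,
  t_mod = fit$t[, "group"],
  p_value = fit$p.value[, "group"]
)
cat(sprintf("d0=%.10g s0_sq=%.10g\n", fit$df.prior, fit$s2.prior))
write.csv(cbind(out, d0 = fit$df.prior, s0_sq = fit$s2.prior),
          "tests/data/limma_fixture_expected.csv", row.names = FALSE)
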