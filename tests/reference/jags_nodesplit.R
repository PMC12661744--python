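# Independent reference run of the node-splitting model with JAGS (rjags).
#
# Fits the same one-stage binomial-logit random-effects node-split model as
# the package on tests/reference/fixture_triangle.csv, splitting A vs B
# (coding A=1, B=2, C=3; reference A; d_dir free, d_ind = d[2] - d[1]),
# with the same priors: N(0, 100^2) on baselines / basic parameters / d_dir
# and LogNormal(-2.56, 1.74) on tau^2.  Chain geometry mirrors the package
# defaults (3 chains, 20000 iterations, 2000 burn-in, thinning 10).
#
# The posterior summaries are frozen into jags_reference.json; the test
# suite compares the package sampler against them within Monte Carlo error.
# Rerun from the repository root with:  Rscript tests/reference/jags_nodesplit.R

library(rjags)
library(coda)

set.seed(2024)

dat <- read.csv("tests/reference/fixture_triangle.csv")
studies <- sort(unique(dat$study))
code <- c(A = 1, B = 2, C = 3)

ns <- length(studies)
r1 <- n1 <- r2 <- n2 <- t1 <- t2 <- direct <- integer(ns)
for (i in seq_along(studies)) {
  rows <- dat[dat$study == studies[i], ]
  rows <- rows[order(code[rows$treatment]), ]
  r1[i] <- rows$events[1]; n1[i] <- rows$sample_size[1]
  r2[i] <- rows$events[2]; n2[i] <- rows$sample_size[2]
  t1[i] <- code[rows$treatment[1]]; t2[i] <- code[rows$treatment[2]]
  direct[i] <- as.integer(t1[i] == 1 && t2[i] == 2)  # two-arm A-B study
}

model_string <- "
model {
  for (i in 1:ns) {
    r1[i] ~ dbin(p1[i], n1[i])
    r2[i] ~ dbin(p2[i], n2[i])
    logit(p1[i]) <- mu[i]
    logit(p2[i]) <- mu[i] + delta[i]
    mu[i] ~ dnorm(0, 1.0E-4)
    delta[i] ~ dnorm(md[i], prec)
    md[i] <- ifelse(direct[i] == 1, ddir, d[t2[i]] - d[t1[i]])
  }
  d[1] <- 0
  d[2] ~ dnorm(0, 1.0E-4)
  d[3] ~ dnorm(0, 1.0E-4)
  ddir ~ dnorm(0, 1.0E-4)
  tau2 ~ dlnorm(-2.56, 0.33030519)   # scale 1.74 -> precision 1/1.74^2
  prec <- 1 / tau2
  tau <- sqrt(tau2)
  dind <- d[2] - d[1]
  IF <- ddir - dind
}
"

jm <- jags.model(
  textConnection(model_string),
  data = list(ns = ns, r1 = r1, n1 = n1, r2 = r2, n2 = n2,
              t1 = t1, t2 = t2, direct = direct),
  n.chains = 3, n.adapt = 2000, quiet = TRUE
)
update(jm, 2000)
samp <- coda.samples(jm, c("ddir", "dind", "IF", "tau"), n.iter = 18000, thin = 10)

stats <- summary(samp)$statistics
out <- list()
for (par in rownames(stats)) {
  out[[par]] <- list(
    mean = unname(stats[par, "Mean"]),
    sd = unname(stats[par, "SD"]),
    ts_se = unname(stats[par, "Time-series SE"])
  )
}
json <- jsonlite::toJSON(out, auto_unbox = TRUE, digits = 8, pretty = TRUE)
writeLines(json, "tests/reference/jags_reference.json")
cat(json, "\n")
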