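# TwoLoversAutoTester.R - entry point
# Generated by the mospec Autocoder from TwoLovers.MoSpec V02.04.03
# Do not edit: regenerate from the model workbook instead.

source("TwoLoversModelPars.R")
source("TwoLoversModelRHS.R")
source("TwoLoversConstraintCheck.R")
source("RK4Solver.R")

T_START <- 0.0
T_END <- 20.0
T_STEP <- 0.01

pars <- ModelPars("Default")
violated <- CheckConstraints(pars)
if (length(violated) > 0) {
  cat("constraint violation; error codes:", violated, "\n")
  quit(status = 3)
}
times <- TimeGrid(T_START, T_END, T_STEP)
y0 <- InitialConditions(pars, times[1])
states <- Integrate(function(tt, yy) ModelRHS(tt, yy, pars), times, y0)
rows <- character(length(times))
for (i in seq_along(times)) {
  alg <- AlgebraicValues(times[i], states[i, ], pars)
  row <- base::c(times[i], states[i, ], alg)
  rows[i] <- paste(sprintf("%.17g", row), collapse = ",")
}
header <- "time,R,J,TotalAffection"
writeLines(base::c(header, rows), "TwoLovers_trajectory.csv")
cat("wrote TwoLovers_trajectory.csv (", length(times), " points)\n")
ok <- try({
  pdf("TwoLovers_plot.pdf")
  matplot(times, states, type = "l", lty = 1, xlab = "time", ylab = "state variables")
  legend("topright", legend = STATE_NAMES, col = seq_along(STATE_NAMES), lty = 1)
  dev.off()
  cat("wrote TwoLovers_plot.pdf\n")
}, silent = TRUE)

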