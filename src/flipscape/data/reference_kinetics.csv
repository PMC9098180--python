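# Published harmonic-TST/graph-transformation kinetic data for base flipping
# in a d(GA)6 DNA duplex (12 bp), per flipped-out state. Input columns only:
# derived quantities (lifetimes, equilibrium constants, decade ratios) are
# recomputed from the rates at run time by flipscape.kinetics.
# groove: the pathway along which the base flips out. angle: CPDb in degrees.
# barriers: free-energy barriers at 300 K in kcal/mol.
base,groove,cpdb_deg,barrier_open_kcal,barrier_close_kcal,k_open_per_s,k_close_per_s
A,major,-172.11,25.51,10.60,1.09e-8,6.37e1
A,minor,126.56,15.35,5.04,1.62e-2,4.54e4
G,major,-47.99,15.50,1.47,1.49e-2,4.55e4
G,major,-122.02,29.19,3.07,1.26e-12,1.62e-1
G,minor,67.00,22.67,5.43,7.67e-8,8.96e-4
G,minor,132.08,25.99,4.28,4.33e-10,8.96e-4
C,major,-45.41,14.39,7.69,7.66e-2,4.97e3
C,major,-124.29,22.84,2.46,5.28e-8,1.02e4
C,major,172.92,26.07,5.52,2.37e-10,2.84e2
C,minor,47.52,15.08,5.75,3.95e-2,4.55e4
T,major,-46.83,11.19,0.80,1.63e1,4.55e4
T,major,177.71,19.29,6.05,3.16e-5,4.82e3
T,minor,76.30,14.39,7.70,7.66e-2,4.97e3
T,minor,121.28,14.79,3.22,2.61e-2,4.97e3
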