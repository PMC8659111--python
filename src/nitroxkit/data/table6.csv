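# Per-molecule hyperfine ledger: equilibrium NO bond length (Angstrom),
# out-of-plane angle theta (deg), B2 equilibrium aN (MHz), 300 K vibrational
# correction dvib (MHz), template-molecule correction dTM (MHz) and cos^2-model
# correction dtheta (MHz).  dCNC (deg) is the CNC-angle difference between the
# molecule and the dimethylnitroxide template at the same theta.
molecule,rNO,dCNC,theta,aN,dvib,dTM,dtheta,note
b,1.267,1.4,12.26,23.12,2.71,0.68,0.63,
c,1.284,8.0,20.13,40.14,1.66,0.44,0.10,
d,1.282,5.6,2.00,25.54,2.62,1.05,0.94,
e,1.283,3.6,0.00,20.11,1.10,0.99,0.95,
f,1.286,3.5,0.00,21.10,2.73,0.99,0.95,
g,1.282,5.1,21.70,40.42,1.14,0.22,-0.03,
h,1.280,5.2,22.79,40.62,2.07,0.09,-0.12,
i,1.281,4.9,21.70,40.18,1.34,0.20,-0.03,
j,1.271,-4.0,2.60,30.82,6.23,1.03,0.93,
k,1.271,-5.7,4.97,31.21,7.17,0.99,0.89,"(R,S) configuration"
l,1.270,-5.1,8.68,32.83,6.22,0.82,0.78,
m,1.270,-4.7,0.00,30.66,5.21,0.98,0.95,
n,1.271,-3.9,0.00,30.64,2.70,0.98,0.95,
o,1.270,-3.9,0.00,30.45,5.47,0.99,0.95,
p,1.270,-7.8,1.80,20.27,4.40,0.98,0.94,
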