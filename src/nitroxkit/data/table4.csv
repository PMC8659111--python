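# Experimental and computed NO-stretching frequencies (cm^-1) for nitroxides a-p.
# nu_exp blank where no reliable experimental assignment exists; medium is the
# recording medium of the experimental band.  nu_H is the printed hybrid value
# (omega_B2 + nu_B3 - omega_B3, rounded) kept for regression against print.
molecule,nu_exp,medium,omega_B3,nu_B3,omega_B2,nu_H,family
b,1397,gas,1439,1410,1437,1408,acyclic
c,1342,KBr,1384,1350,1359,1325,acyclic
d,1370,KBr,1412,1379,1387,1354,acyclic
e,1342,tBuOH,1392,1360,1379,1347,acyclic
f,1346,tBuOH,1400,1369,1392,1361,acyclic
g,1339,tBuOH,1377,1345,1368,1336,six-ring
h,1380,CCl4,1392,1362,1398,1367,six-ring
i,1371,CCl4,1401,1370,1397,1366,six-ring
j,,,1472,1440,1453,1421,five-ring-sat
k,,,1485,1456,1461,1432,five-ring-sat
l,1438,Nujol,1481,1453,1457,1429,five-ring-unsat
m,1435,Nujol,1487,1455,1460,1427,five-ring-unsat
n,1428,Nujol,1486,1452,1458,1424,five-ring-unsat
o,1427,tBuOH,1488,1454,1465,1431,five-ring-unsat
p,,,1468,1438,1456,1426,five-ring-unsat
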