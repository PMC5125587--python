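accession,origin,year,cai,enc,gc3s,gc,u3s,c3s,a3s,g3s,gravy,aromo,gc12,gc3
LC002520,Uganda,1947,0.737,52.94,50.80,50.70,24.97,31.64,34.21,31.23,-0.140,0.080,49.07,53.94
KF383116,Senegal,1968,0.739,52.58,51.20,51.00,24.78,31.71,33.85,31.73,-0.142,0.079,49.22,54.38
EU545988,Micronesia,1968,0.735,53.64,51.80,51.00,25.28,31.93,32.65,32.28,-0.148,0.081,49.11,54.88
KJ776791,Polynesia,2013,0.735,53.36,52.00,51.10,24.84,32.19,32.85,32.27,-0.147,0.081,49.11,55.08
KU312312,Suriname,2015,0.735,53.40,52.00,51.10,24.79,32.24,32.86,32.24,-0.147,0.081,49.15,55.08
KU321639,Brazil,2015,0.736,53.28,52.00,51.10,24.85,32.24,32.82,32.23,-0.148,0.081,49.11,55.11
KF383119,Senegal,2001,0.738,52.92,50.80,50.90,25.00,31.70,34.07,31.19,-0.139,0.079,49.24,54.03
KF383118,Senegal,2001,0.741,52.67,50.80,50.80,24.99,31.52,34.12,31.32,-0.151,0.078,49.14,54.03
KF383115,Central African Republic,1968,0.738,52.56,50.00,50.50,25.68,30.97,34.42,31.03,-0.140,0.080,48.98,53.13
KF268949,Central African Republic,1980,0.737,52.69,49.60,50.40,25.74,31.09,34.90,30.34,-0.142,0.080,49.08,52.87
KF268948,Central African Republic,1979,0.739,52.64,49.90,50.40,25.67,31.24,34.59,30.57,-0.141,0.080,49.07,53.17
KF268950,Central African Republic,1976,0.739,52.67,49.90,50.40,25.67,31.24,34.61,30.55,-0.140,0.080,49.07,53.14
KF383117,Senegal,1997,0.735,52.77,50.30,50.60,25.66,30.72,34.03,31.68,-0.141,0.080,49.04,53.42
KU509998,Haiti,2014,0.736,53.30,52.00,51.10,24.85,32.24,32.82,32.22,-0.148,0.081,49.12,55.11
KU501217,Guatemala,2015,0.735,53.15,51.90,51.10,24.82,32.23,33.07,32.03,-0.144,0.081,49.11,54.91
KU365777,Brazil,2015,0.735,53.27,51.90,51.10,24.83,32.22,32.95,32.14,-0.147,0.081,49.14,54.99
KU501216,Guatemala,2015,0.735,53.18,51.80,51.00,24.85,32.20,33.07,32.03,-0.144,0.081,49.11,54.88
KU501215,Puerto Rico,2015,0.735,53.25,52.10,51.10,24.65,32.40,32.95,32.12,-0.147,0.081,49.12,55.14
KU365780,Brazil,2015,0.735,53.27,51.90,51.10,24.87,32.18,32.95,32.14,-0.147,0.081,49.14,54.96
KU365779,Brazil,2015,0.735,53.29,51.90,51.10,24.87,32.18,32.95,32.14,-0.147,0.081,49.12,54.96
KU365778,Brazil,2015,0.735,53.34,51.90,51.10,24.83,32.22,33.03,32.05,-0.147,0.081,49.14,54.94
KU647676,Martinique,2015,0.735,53.21,51.90,51.10,24.82,32.24,33.07,32.00,-0.146,0.081,49.12,54.94
KU866423,China,2016,0.735,53.32,52.00,51.10,24.70,32.27,32.96,32.24,-0.147,0.081,49.14,55.11
KU870645,USA,2016,0.734,53.29,51.90,51.10,24.89,32.12,32.96,32.16,-0.142,0.080,49.14,54.91
KU926310,Brazil,2016,0.735,53.28,52.00,51.10,24.72,32.32,32.98,32.12,-0.147,0.081,49.12,55.05
KU926309,Brazil,2016,0.736,53.22,52.10,51.20,24.67,32.31,32.86,32.30,-0.146,0.081,49.12,55.17
KU922960,Mexico,2016,0.736,53.21,51.90,51.10,24.83,32.23,33.05,32.03,-0.147,0.081,49.10,54.94
KU820898,China,2016,0.736,53.27,51.90,51.10,24.73,32.27,33.09,32.04,-0.146,0.081,49.14,54.96
KU853013,Italy,2016,0.736,53.23,52.00,51.10,24.72,32.33,33.04,32.01,-0.146,0.081,49.17,54.99
KU853012,Italy,2016,0.736,53.27,52.00,51.10,24.74,32.35,32.99,32.04,-0.147,0.081,49.15,55.02
KU955591,Senegal,1984,0.740,52.67,51.20,51.00,24.91,31.58,33.73,31.91,-0.143,0.080,49.21,54.41
KU955592,Senegal,1984,0.740,52.67,51.20,50.90,24.94,31.54,33.69,31.96,-0.143,0.080,49.19,54.41
KU955593,Cambodia,2010,0.735,53.53,51.60,51.00,25.40,31.72,32.74,32.31,-0.148,0.081,49.17,54.73
KU955594,Uganda,1947,0.738,52.89,50.90,50.80,24.79,31.80,34.20,31.25,-0.139,0.080,49.09,54.09
KU955595,Senegal,1984,0.740,52.68,51.30,51.00,24.87,31.61,33.69,31.96,-0.143,0.079,49.19,54.47
KX056898,China,2016,0.735,53.27,51.70,51.10,24.94,32.06,33.08,32.05,-0.147,0.081,49.17,54.82
KU681082,Philippines,2012,0.735,53.55,51.50,51.00,25.29,31.69,33.04,32.07,-0.149,0.081,49.14,54.59
KU681081,Thailand,2014,0.735,53.56,51.90,51.10,24.77,32.34,33.00,31.96,-0.146,0.081,49.17,55.02
KU761564,China,2016,0.736,53.25,51.90,51.10,24.76,32.26,33.03,32.09,-0.146,0.081,49.14,54.99
KU729218,Brazil,2015,0.735,53.33,52.00,51.10,24.93,32.09,32.81,32.31,-0.148,0.081,49.14,54.99
KU744693,China,2016,0.737,53.29,52.10,51.20,24.77,32.43,32.75,32.07,-0.147,0.081,49.24,55.20
KU729217,Brazil,2015,0.736,53.21,52.00,51.10,24.71,32.31,32.99,32.16,-0.146,0.081,49.15,55.02
KU720415,Uganda,1947,0.738,52.91,50.90,50.70,24.86,31.75,34.21,31.23,-0.140,0.080,49.07,54.03
KU497555,Brazil,2015,0.736,53.26,52.00,51.10,24.68,32.32,33.04,32.11,-0.145,0.081,49.11,55.05
KU707826,Brazil,2015,0.735,53.29,51.90,51.10,24.87,32.18,32.95,32.14,-0.147,0.081,49.12,54.96
KU527068,Brazil,2015,0.735,53.38,52.00,51.10,24.75,32.28,32.94,32.18,-0.144,0.081,49.13,55.05
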