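-----BEGIN PUBLIC KEY-----
MIIBIjANBgkqhkiG9w0BAQEFAAOCAQ8AMIIBCgKCAQEAw4C0OI6Evwfn7Z2HRyJu
NR4LwudOhJqVRandHXAIW0HOJKPpqHNX0VgQaK9JTQvTplnjnwtJrVtRgUT0Wjxv
nGanftQJ4R+kwsT4v/dyuhrBG+2pH39Ilj2GbrMaG8aL/JQ1VNBT7Pn99VyWyHhr
+OVs/k/fafsFl+YmE8h7QCVJwTu8rnlXlfTcTigVvcK7EaMc13hgtr6Zv+BLZLoB
12MYLC+8HK3usIW40LBW10HmGsiu+1hytWBGVztPJu/jmfxV77UFWSsQsBqwAicn
RZ5hba1+fju6lM66u3K3yM3Uhd+1DWzIp/jkmu8tZxlZMKl5M5aQEthpTC6J0RKA
0QIDAQAB
-----END PUBLIC KEY-----
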