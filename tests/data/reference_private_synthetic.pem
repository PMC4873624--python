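-----BEGIN PRIVATE KEY-----
MIIEvgIBADANBgkqhkiG9w0BAQEFAASCBKgwggSkAgEAAoIBAQDDgLQ4joS/B+ft
nYdHIm41HgvC506EmpVFqd0dcAhbQc4ko+moc1fRWBBor0lNC9OmWeOfC0mtW1GB
RPRaPG+cZqd+1AnhH6TCxPi/93K6GsEb7akff0iWPYZusxobxov8lDVU0FPs+f31
XJbIeGv45Wz+T99p+wWX5iYTyHtAJUnBO7yueVeV9NxOKBW9wrsRoxzXeGC2vpm/
4EtkugHXYxgsL7wcre6whbjQsFbXQeYayK77WHK1YEZXO08m7+OZ/FXvtQVZKxCw
GrACJydFnmFtrX5+O7qUzrq7crfIzdSF37UNbMin+OSa7y1nGVkwqXkzlpAS2GlM
LonREoDRAgMBAAECggEAAl+nKhw5qpOyS+IpDALA5/5ksfaayPH5h8sZE99SDEDM
LtZNb9qkQWntm3lfwFw5TLoNqr1f2FRIaCawRgIy1rX8wmwmCVvLGJ3jAuDcJAjo
7E/74pW28DM9O4ELYZsmnify59DQHAuPx+SNl7YcLxbvnLzXUqzJQH/H8yu9d1j9
hM7oflOz8N1wl1NedHWdXxLUYGZYal0vzqLuRtnVDSQeAAUZcC1NMFSLPMZ+aieb
GnFNyLgaNcxXD1AMRfxTDG0euZrSFkh811dyXdqyv0Fufmo2HxZcqtmEWSi5WXZT
w4dQIBAXWTkcvg+Vsot/j9XqTrgYhw0C48yakZIBOQKBgQDhZRNIra2lDUYGwD7o
x9k4yZIUbQwBu7IlEpL/7O/CenrQ8asgj1gFm6s4u0QmrBdnLvM8fhkNHZxkNSZz
X80Bz9/51CscBq22vfcvc2UClVuJHIr40/DPhOaYCX8bsiaG7u/3m5BZHhVuYoyO
pnPoxlcofCYf7N8fG2RLMzCWxQKBgQDeDI2zZ5bhOiewmUfd5w7aDZNp4+a4QezG
UwtuvEBKDYv+N11/sqzzAz6RjCF0ImiJ6KV4A/4DFEIcelRO2YH5Y1xNlvB7OakI
y9tV7Z2P741Xcwse57+PRN5SzSWKE3nVmUrmmgouk66EKOa8T1Wl6HJgukT1GqLs
sVKrDD6CnQKBgF1X452Ut7YEAj0nfqYepbob2FB3PKK3Hba2s4QjlsOev6AqhWlN
k/F2n3k2LKorWOHVksw5mJxS6AKj9FGRmjAm66XmFRhdN7HXiDfxfSKNwkPNO0yD
UVZPvsO2IxrQM55r85tCpIwTpmJ5k6Y8DwKWqV/N0mgkS97xFB8EixnVAoGBAKXH
V4/G2iWjRniZp8crN7Jiill3Vgzg40aaP6HYGGNxQ8BzU3IAUxFHrdH6fgt3mPbF
Y6x7xoxD9qvORN1tlJU9sm8XLsnBHcs8b6/yrD0HC05rzLSxLxpmv1mwYcN5kO+A
+CO8g7eMeLGg28thq78nESXYS5122oa+SMr9ZDodAoGBALeH41mtCzSMkVfDlPnT
P2FKdUZ5GXI7aG2BZPtCT+dtWiVDdm2RckT64hnuN1+MTpSd7Mv0dqV8KPyTSY3H
EOUN+ry+d/UVNKsr2+yfY+IYqI1iPx5GEJ6uaH9yLNJhyVfimJiXxzA4NgyfveOL
NHRxoirJhUEr0UDDRNtJWq51
-----END PRIVATE KEY-----
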